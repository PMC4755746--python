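"""Simulation of RA and PC mechanoreceptive afferents.

Each afferent is a noise-free leaky integrate-and-fire (LIF) unit driven
by a weighted sum of six rectified stimulus features: positive and
negative half-wave rectified position, velocity, and acceleration of the
skin displacement.  The position trace is optionally pre-smoothed with a
Gaussian window, which models the roll-off of Pacinian sensitivity above
roughly 300 Hz, and the drive can be delayed to model conduction delay.

Membrane dynamics::

    dv/dt = (-v + drive(t - delay)) / tau_m

with a spike whenever v crosses the threshold, reset to ``reset`` and an
absolute refractory period.  The integrator is the exact exponential
update for piecewise-constant drive, and threshold crossings are located
in closed form within a step, so simulated inter-spike intervals match
the analytic LIF solution to high precision.

Population responses are per-class averages of 1-ms binned spike counts
(spikes/s), the quantities the cortical encoding model consumes.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter1d

from .stimulus import StimulusTrace, make_sinusoid

RA = "RA"
PC = "PC"

BIN_MS = 1.0  # population-rate bin width used throughout the pipeline


@dataclasses.dataclass
class AfferentModel:
    """Integrate-and-fire model of a single mechanoreceptive afferent.

    ``feature_weights`` gain the six rectified channels in fixed order
    [x]+, [-x]+, [dx]+, [-dx]+, [d2x]+, [-d2x]+ with units of drive per
    µm, per µm/s and per µm/s² respectively.
    """

    afferent_class: str
    feature_weights: np.ndarray
    smoothing_sigma_ms: float = 0.0
    delay_ms: float = 0.0
    tau_m_ms: float = 5.0
    threshold: float = 1.0
    reset: float = 0.0
    t_refractory_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.afferent_class not in (RA, PC):
            raise ValueError(f"afferent_class must be {RA!r} or {PC!r}")
        w = np.asarray(self.feature_weights, dtype=np.float64)
        if w.shape != (6,):
            raise ValueError("feature_weights must have exactly 6 entries")
        self.feature_weights = w
        if not self.tau_m_ms > 0:
            raise ValueError("tau_m_ms must be positive")
        if not self.threshold > self.reset:
            raise ValueError("threshold must exceed reset")
        if self.t_refractory_ms < 0 or self.smoothing_sigma_ms < 0 or self.delay_ms < 0:
            raise ValueError("t_refractory_ms, smoothing_sigma_ms, delay_ms must be >= 0")


@dataclasses.dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) within [0, duration)."""

    spike_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=np.float64)
        if t.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike_times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] >= self.duration):
            raise ValueError("spike_times must lie in [0, duration)")
        object.__setattr__(self, "spike_times", t)

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def rate(self) -> float:
        """Mean firing rate in spikes/s."""
        return self.n_spikes / self.duration

    def binned(self, bin_ms: float = BIN_MS) -> np.ndarray:
        """Spike counts in consecutive bins of ``bin_ms`` milliseconds."""
        n_bins = int(np.ceil(self.duration * 1000.0 / bin_ms))
        idx = np.floor(self.spike_times * 1000.0 / bin_ms).astype(np.int64)
        return np.bincount(idx, minlength=n_bins).astype(np.float64)


@dataclasses.dataclass
class PopulationResponse:
    """1-ms binned RA and PC population firing rates (spikes/s).

    These are the two input channels of the cortical encoding model;
    the z-scored version (zero mean, unit SD over the fitting set) is
    what the linear filters act on.
    """

    ra_rate: np.ndarray
    pc_rate: np.ndarray
    zscored: bool = False
    z_params: dict | None = None

    def __post_init__(self) -> None:
        self.ra_rate = np.asarray(self.ra_rate, dtype=np.float64)
        self.pc_rate = np.asarray(self.pc_rate, dtype=np.float64)
        if self.ra_rate.shape != self.pc_rate.shape:
            raise ValueError("ra_rate and pc_rate must have equal length")
        if not self.zscored and (np.any(self.ra_rate < 0) or np.any(self.pc_rate < 0)):
            raise ValueError("raw population rates must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.ra_rate.size

    def zscore(self, z_params: dict | None = None) -> "PopulationResponse":
        """Return a z-scored copy; computes parameters if not supplied."""
        if self.zscored:
            raise ValueError("population response is already z-scored")
        if z_params is None:
            z_params = {
                "ra_mean": float(np.mean(self.ra_rate)),
                "ra_sd": float(np.std(self.ra_rate)) or 1.0,
                "pc_mean": float(np.mean(self.pc_rate)),
                "pc_sd": float(np.std(self.pc_rate)) or 1.0,
            }
        return PopulationResponse(
            (self.ra_rate - z_params["ra_mean"]) / z_params["ra_sd"],
            (self.pc_rate - z_params["pc_mean"]) / z_params["pc_sd"],
            zscored=True,
            z_params=dict(z_params),
        )


def zscore_populations(pops: Sequence[PopulationResponse]) -> tuple[list[PopulationResponse], dict]:
    """Z-score a set of population responses with shared parameters.

    Parameters are computed once by pooling all responses (the fitting
    set) and frozen, so that predictions on new data use the same scale.
    """
    ra = np.concatenate([p.ra_rate for p in pops])
    pc = np.concatenate([p.pc_rate for p in pops])
    z_params = {
        "ra_mean": float(np.mean(ra)),
        "ra_sd": float(np.std(ra)) or 1.0,
        "pc_mean": float(np.mean(pc)),
        "pc_sd": float(np.std(pc)) or 1.0,
    }
    return [p.zscore(z_params) for p in pops], z_params


# --------------------------------------------------------------------------
# rectified features and LIF simulation
# --------------------------------------------------------------------------

def rectified_features(trace: StimulusTrace, smoothing_sigma_ms: float = 0.0) -> np.ndarray:
    """Six-channel rectified feature series of a displacement trace.

    Returns an (n_samples, 6) array with channels, in order,
    [x]+, [-x]+, [dx]+, [-dx]+, [d2x]+, [-d2x]+ (µm, µm/s, µm/s²).
    Gaussian smoothing of width ``smoothing_sigma_ms`` is applied to the
    position trace *before* differentiation.
    """
    x = trace.samples
    fs = trace.sample_rate
    if smoothing_sigma_ms > 0:
        sigma_samples = smoothing_sigma_ms * 1e-3 * fs
        x = gaussian_filter1d(x, sigma_samples, mode="nearest")
    dt = 1.0 / fs
    v = np.gradient(x, dt)
    a = np.gradient(v, dt)
    feats = np.empty((x.size, 6))
    feats[:, 0] = np.maximum(x, 0.0)
    feats[:, 1] = np.maximum(-x, 0.0)
    feats[:, 2] = np.maximum(v, 0.0)
    feats[:, 3] = np.maximum(-v, 0.0)
    feats[:, 4] = np.maximum(a, 0.0)
    feats[:, 5] = np.maximum(-a, 0.0)
    return feats


@njit(cache=True)
def _lif_spikes(drive, dt, tau, threshold, reset, t_ref):  # pragma: no cover
    n = drive.shape[0]
    out = np.empty(n, dtype=np.float64)
    n_out = 0
    v = 0.0
    t_free = 0.0  # absolute time at which the refractory period ends
    for i in range(n):
        t0 = i * dt
        t1 = t0 + dt
        d = drive[i]
        pos = t0
        if t_free > t0:
            if t_free >= t1:
                continue  # whole step inside refractory period
            pos = t_free
            v = reset
        # integrate from pos to t1 with constant drive d; a step can hold
        # several spikes only when t_ref < dt
        while True:
            if d > threshold and v < threshold:
                # closed-form threshold crossing time for the exponential
                # relaxation v(s) = d + (v - d) * exp(-s/tau)
                t_spike = pos + tau * np.log((d - v) / (d - threshold))
                if t_spike < t1 and n_out < n:
                    out[n_out] = t_spike
                    n_out += 1
                    t_free = t_spike + t_ref
                    v = reset
                    if t_free >= t1:
                        break  # refractory covers rest of step
                    pos = t_free
                    continue
            v = d + (v - d) * np.exp(-(t1 - pos) / tau)
            break
    return out[:n_out]


def simulate_afferent(
    model: AfferentModel, trace: StimulusTrace, dt_ms: float = 0.05
) -> SpikeTrain:
    """Simulate one afferent's noise-free response to a stimulus trace.

    ``dt_ms`` must divide the trace's sampling interval or equal it;
    drive samples are held piecewise constant over each step.
    """
    if dt_ms > 0.1:
        raise ValueError("dt_ms must be <= 0.1 ms for stable spike timing")
    fs_dt_ms = 1000.0 / trace.sample_rate
    feats = rectified_features(trace, model.smoothing_sigma_ms)
    drive = feats @ model.feature_weights
    if not np.isclose(dt_ms, fs_dt_ms):
        # resample drive onto the simulation grid by zero-order hold
        n_steps = int(round(trace.duration * 1000.0 / dt_ms))
        src = np.minimum(
            (np.arange(n_steps) * dt_ms / fs_dt_ms).astype(np.int64), drive.size - 1
        )
        drive = drive[src]
    if model.delay_ms > 0:
        shift = int(round(model.delay_ms / dt_ms))
        drive = np.concatenate([np.zeros(shift), drive[: drive.size - shift]])
    dt_s = dt_ms * 1e-3
    times = _lif_spikes(
        drive,
        dt_s,
        model.tau_m_ms * 1e-3,
        model.threshold,
        model.reset,
        model.t_refractory_ms * 1e-3,
    )
    times = times[times < trace.duration]
    return SpikeTrain(times, trace.duration)


def population_rate(
    models: Iterable[AfferentModel],
    trace: StimulusTrace,
    dt_ms: float = 0.05,
    require_both: bool = True,
) -> PopulationResponse:
    """Average 1-ms binned firing rate of RA and PC model populations.

    Each class's rate is the mean over that class's models of the 1-ms
    binned spike counts, expressed in spikes/s.
    """
    models = list(models)
    n_bins = int(np.ceil(trace.duration * 1000.0 / BIN_MS))
    sums = {RA: np.zeros(n_bins), PC: np.zeros(n_bins)}
    counts = {RA: 0, PC: 0}
    for m in models:
        st = simulate_afferent(m, trace, dt_ms)
        sums[m.afferent_class] += st.binned(BIN_MS)
        counts[m.afferent_class] += 1
    if require_both and (counts[RA] == 0 or counts[PC] == 0):
        raise ValueError("population requires at least one model of each class")
    ra = sums[RA] / max(counts[RA], 1) / (BIN_MS * 1e-3)
    pc = sums[PC] / max(counts[PC], 1) / (BIN_MS * 1e-3)
    return PopulationResponse(ra, pc)


# --------------------------------------------------------------------------
# default synthetic afferent populations
# --------------------------------------------------------------------------
#
# The class parameterizations below are synthetic stand-ins, not fits to
# real fibers.  RA units weight positive-going velocity with a wide
# Gaussian pre-filter (sigma 2 ms): velocity grows with frequency while
# the smoothing cuts it back, so RA sensitivity peaks in the flutter
# range (~80 Hz) and dies off above ~300 Hz, and RA spike timing is
# correspondingly less precise.  PC units weight positive-going
# acceleration with lighter smoothing (sigma 0.8 ms): sensitivity peaks
# near 280 Hz and rolls off above ~300 Hz, with millisecond-precise
# locking.  Drive comes from the positive-going channels only, so it
# dips below threshold every stimulus cycle: units entrain to cycles
# instead of firing at the refractory ceiling, producing entrainment
# plateaus and physiological few-hundred-Hz rates.

_RA_WEIGHTS = np.array([0.0, 0.0, 1.94e-3, 0.0, 0.0, 0.0])
_PC_WEIGHTS = np.array([0.0, 0.0, 0.0, 0.0, 2.03e-6, 0.0])


def default_ra_model(**overrides) -> AfferentModel:
    kwargs = dict(
        afferent_class=RA,
        feature_weights=_RA_WEIGHTS.copy(),
        smoothing_sigma_ms=2.0,
        delay_ms=2.0,
        tau_m_ms=5.0,
        threshold=1.0,
        reset=0.0,
        t_refractory_ms=1.0,
    )
    kwargs.update(overrides)
    return AfferentModel(**kwargs)


def default_pc_model(**overrides) -> AfferentModel:
    kwargs = dict(
        afferent_class=PC,
        feature_weights=_PC_WEIGHTS.copy(),
        smoothing_sigma_ms=0.8,
        delay_ms=2.0,
        tau_m_ms=5.0,
        threshold=1.0,
        reset=0.0,
        t_refractory_ms=1.0,
    )
    kwargs.update(overrides)
    return AfferentModel(**kwargs)


def make_population(
    n_ra: int = 14, n_pc: int = 4, seed: int | np.random.Generator = 0
) -> list[AfferentModel]:
    """A jittered population of RA and PC afferent models.

    Defaults to 14 RA and 4 PC units.  Weights are log-normally jittered
    (20%) and thresholds spread over roughly a decade (log-normal, 60%)
    across units, so individual fibers differ substantially in
    sensitivity — the population-averaged rate then grades smoothly with
    stimulus amplitude even though each unit's own rate-intensity
    function is a staircase of entrainment plateaus.  Response delays
    disperse over ~6 ms across RA units but only ~1 ms across PC units,
    so the pooled RA signal is temporally smeared while the pooled PC
    signal keeps millisecond precision, as in the real populations.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pop: list[AfferentModel] = []
    for factory, n, delay_spread in (
        (default_ra_model, n_ra, 6.0),
        (default_pc_model, n_pc, 1.0),
    ):
        for _ in range(n):
            base = factory()
            w = base.feature_weights * rng.lognormal(0.0, 0.20, size=6)
            thr = base.threshold * rng.lognormal(0.0, 0.60)
            delay = base.delay_ms + rng.uniform(0.0, delay_spread)
            pop.append(
                factory(feature_weights=w, threshold=thr, delay_ms=delay)
            )
    return pop


# --------------------------------------------------------------------------
# van Rossum distance and afferent fitting
# --------------------------------------------------------------------------

def van_rossum_distance(a: SpikeTrain, b: SpikeTrain, tau_ms: float) -> float:
    """van Rossum spike-train distance with causal exponential kernel.

    Normalized so that the squared distance between a single-spike train
    and the empty train equals 1/2 (the original convention, kernel
    ``exp(-t/tau)/sqrt(tau)``).  Computed in closed form from pairwise
    spike-time differences.
    """
    if not tau_ms > 0:
        raise ValueError("tau_ms must be positive")
    tau = tau_ms * 1e-3
    ta, tb = a.spike_times, b.spike_times

    def cross(u: np.ndarray, w: np.ndarray) -> float:
        if u.size == 0 or w.size == 0:
            return 0.0
        return float(np.sum(np.exp(-np.abs(u[:, None] - w[None, :]) / tau)))

    d2 = 0.5 * (cross(ta, ta) + cross(tb, tb) - 2.0 * cross(ta, tb))
    return float(np.sqrt(max(d2, 0.0)))


@dataclasses.dataclass
class AfferentFit:
    """Result of a derivative-free afferent-model fit."""

    model: AfferentModel
    initial_cost: float
    final_cost: float
    converged: bool


def _fit_cost(
    model: AfferentModel,
    targets: Sequence[SpikeTrain],
    stimuli: Sequence[StimulusTrace],
    tau_ms: float,
    dt_ms: float,
) -> float:
    c = 0.0
    for st, stim in zip(targets, stimuli):
        pred = simulate_afferent(model, stim, dt_ms)
        c += van_rossum_distance(pred, st, tau_ms) ** 2
    return c


def fit_afferent_model(
    target_spikes: Sequence[SpikeTrain],
    stimuli: Sequence[StimulusTrace],
    init: AfferentModel,
    stimulus_labels: Sequence[str] | None = None,
    schedule: Sequence[tuple[str, float]] | None = None,
    dt_ms: float = 0.05,
    max_sweeps: int = 30,
    step_init: float = 0.25,
    step_min: float = 0.01,
) -> AfferentFit:
    """Fit afferent feature weights by direct (compass) search.

    Minimizes the summed squared van Rossum distance between simulated
    and target spike trains.  The search follows a schedule of
    (stimulus-set label, kernel time constant) stages — canonically noise
    first, then alternating sinusoid/diharmonic sets with decreasing tau
    — multiplicatively perturbing one weight at a time and shrinking the
    step when no move improves the cost.  The best model found is always
    returned; ``converged`` is False if the final stage hit its sweep cap
    while still improving.
    """
    if len(target_spikes) != len(stimuli):
        raise ValueError("target_spikes and stimuli must be aligned")
    if stimulus_labels is None:
        stimulus_labels = ["noise"] * len(stimuli)
    if schedule is None:
        taus = [8.0, 4.0, 2.0]
        labels = sorted(set(stimulus_labels), reverse=True)  # noise first
        schedule = [(lab, tau) for tau in taus for lab in labels]

    weights = init.feature_weights.copy()
    zero_init = not np.any(weights != 0)

    def with_weights(w: np.ndarray) -> AfferentModel:
        return dataclasses.replace(init, feature_weights=w.copy())

    initial_cost = None
    final_cost = None
    converged = True
    for label, tau_ms in schedule:
        idx = [i for i, lab in enumerate(stimulus_labels) if lab == label]
        if not idx:
            continue
        tgt = [target_spikes[i] for i in idx]
        stm = [stimuli[i] for i in idx]
        best = _fit_cost(with_weights(weights), tgt, stm, tau_ms, dt_ms)
        if initial_cost is None:
            initial_cost = best
        if best == 0.0 or zero_init:
            final_cost = best
            continue
        step = step_init
        sweeps = 0
        while step >= step_min and sweeps < max_sweeps:
            improved = False
            for j in range(6):
                base = weights[j]
                for factor in (1.0 + step, 1.0 / (1.0 + step)):
                    trial = weights.copy()
                    trial[j] = base * factor if base != 0 else step * factor
                    c = _fit_cost(with_weights(trial), tgt, stm, tau_ms, dt_ms)
                    if c < best - 1e-12:
                        best, weights = c, trial
                        improved = True
                        break
            if not improved:
                step *= 0.5
            sweeps += 1
        if sweeps >= max_sweeps and step >= step_min:
            converged = False
            warnings.warn("afferent fit stage hit sweep cap; best-so-far returned")
        final_cost = best
    if initial_cost is None:
        raise ValueError("schedule matched no stimuli")
    return AfferentFit(with_weights(weights), initial_cost, final_cost, converged)


# --------------------------------------------------------------------------
# threshold helpers (sensitivity curves)
# --------------------------------------------------------------------------

def tuning_threshold_amplitude(
    model: AfferentModel,
    frequency: float,
    duration: float = 0.5,
    amp_bounds: tuple[float, float] = (1e-4, 1e4),
    tol: float = 0.01,
) -> float:
    """Amplitude (µm) at which the model fires one spike per stimulus
    cycle of a sinusoid at ``frequency`` — the entrainment ("tuning")
    threshold.  Found by bisection on the mean rate against the target
    rate ``frequency`` (one spike per cycle)."""
    lo, hi = amp_bounds

    def rate(amp: float) -> float:
        st = simulate_afferent(model, make_sinusoid(frequency, amp, duration))
        return st.rate()

    # onset transients clip a couple of cycles, so the 1-spike-per-cycle
    # plateau sits just under f
    target = frequency - 3.0 / duration
    if rate(hi) < target:
        raise ValueError("upper amplitude bound cannot drive 1 spike/cycle")
    while hi / lo > 1 + tol:
        mid = np.sqrt(lo * hi)
        if rate(mid) >= target:
            hi = mid
        else:
            lo = mid
    return float(hi)


def absolute_threshold_amplitude(
    model: AfferentModel,
    frequency: float,
    duration: float = 0.5,
    amp_bounds: tuple[float, float] = (1e-4, 1e4),
    tol: float = 0.01,
) -> float:
    """Smallest sinusoid amplitude (µm) that elicits any spike."""
    lo, hi = amp_bounds

    def n_spikes(amp: float) -> int:
        return simulate_afferent(model, make_sinusoid(frequency, amp, duration)).n_spikes

    if n_spikes(hi) == 0:
        raise ValueError("upper amplitude bound elicits no spikes")
    while hi / lo > 1 + tol:
        mid = np.sqrt(lo * hi)
        if n_spikes(mid) > 0:
            hi = mid
        else:
            lo = mid
    return float(hi)
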