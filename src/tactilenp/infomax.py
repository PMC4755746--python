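"""Information-maximizing filter optimization (efficient coding).

Given texture-analog skin vibrations, the question is: which RA/PC
filters make an LNP neuron's spikes maximally informative about the
instantaneous vibration amplitude?  The objective is the mutual
information between the binary spike variable S and the binned
amplitude variable V,

    I(S, V) = sum_s sum_v p(s, v) log2[ p(s, v) / (p(s) p(v)) ]

where p(v) is the empirical distribution of the absolute deflection
amplitude in 1-ms bins (50 equal-width bins), p(s=1 | v) is the mean
LNP spiking probability over the time bins whose stimulus amplitude —
read 15 ms before the response, mimicking cortical response latency —
falls in bin v, and the mean firing probability is constrained so
optimized neurons fire at physiological rates.

The gradient of I with respect to the 200 filter values is analytic
(chain rule through p(s|v) and the piecewise-linear rectifier), and the
optimization is equality-constrained gradient ascent (SLSQP) from
multiple random starts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.optimize

from .cortex_lnp import CorticalFilterPair, LaggedDesign, Nonlinearity
from .periphery import AfferentModel, population_rate, zscore_populations
from .stimulus import StimulusTrace

N_AMPLITUDE_BINS = 50
DELAY_MS = 15
LN2 = np.log(2.0)


# --------------------------------------------------------------------------
# stimulus amplitude distribution
# --------------------------------------------------------------------------

def bin_amplitudes(trace: StimulusTrace, bin_ms: float = 1.0) -> np.ndarray:
    """Absolute deflection amplitude sampled once per 1-ms bin."""
    step = int(round(bin_ms * 1e-3 * trace.sample_rate))
    return np.abs(trace.samples[::step])


def stimulus_distribution(
    traces: Sequence[StimulusTrace], n_bins: int = N_AMPLITUDE_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical distribution p(v) of per-1-ms absolute amplitudes.

    Pools all traces, divides the observed range into ``n_bins``
    equal-width bins and returns (p_v, edges); p_v sums to one.
    """
    if not traces:
        raise ValueError("need at least one trace")
    amps = np.concatenate([bin_amplitudes(t) for t in traces])
    if np.ptp(amps) == 0:
        raise ValueError("constant trace: amplitude distribution is degenerate")
    counts, edges = np.histogram(amps, bins=n_bins)
    p_v = counts / counts.sum()
    return p_v, edges


# --------------------------------------------------------------------------
# MI problem container
# --------------------------------------------------------------------------

@dataclasses.dataclass
class MIProblem:
    """A fully prepared mutual-information optimization problem.

    Holds the lagged design of the (z-scored, scaled) afferent responses
    to the texture set, the amplitude-bin index of every valid time bin
    (amplitude read ``delay_ms`` before the response bin), the amplitude
    distribution p(v) over those bins, the fixed nonlinearity and the
    rate constraint.
    """

    W: np.ndarray  # (n_valid_bins, 200) lagged design rows
    v_idx: np.ndarray  # amplitude bin per valid row
    p_v: np.ndarray
    v_edges: np.ndarray
    nl: Nonlinearity
    rate_target: float
    delay_ms: int = DELAY_MS
    scale_ra: float = 1.0
    scale_pc: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rate_target < 1.0:
            raise ValueError("rate_target must lie in (0, 1)")
        if self.delay_ms < 0:
            raise ValueError("delay_ms must be >= 0")
        if not np.isclose(self.p_v.sum(), 1.0):
            raise ValueError("p_v must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.p_v.size

    @property
    def bin_counts(self) -> np.ndarray:
        return np.bincount(self.v_idx, minlength=self.n_bins)


def build_mi_problem(
    traces: Sequence[StimulusTrace],
    afferent_models: Sequence[AfferentModel],
    nl: Nonlinearity,
    rate_target: float = 0.05,
    delay_ms: int = DELAY_MS,
    n_bins: int = N_AMPLITUDE_BINS,
    scale_ra: float = 1.0,
    scale_pc: float = 1.0,
    dt_ms: float = 0.05,
) -> MIProblem:
    """Simulate afferent responses to the texture set and assemble the
    MI problem.

    ``scale_ra``/``scale_pc`` multiply each trace before driving the
    corresponding afferent class (the global scaling that matches
    population rates to texture-evoked levels; see
    ``calibrate_scaling``).  Responses are z-scored over the texture
    set, as in filter estimation.
    """
    pops = []
    for tr in traces:
        pr_ra = population_rate(
            [m for m in afferent_models if m.afferent_class == "RA"],
            StimulusTrace(tr.samples * scale_ra, tr.sample_rate),
            dt_ms,
            require_both=False,
        )
        pr_pc = population_rate(
            [m for m in afferent_models if m.afferent_class == "PC"],
            StimulusTrace(tr.samples * scale_pc, tr.sample_rate),
            dt_ms,
            require_both=False,
        )
        pops.append(
            dataclasses.replace(pr_ra, pc_rate=pr_pc.pc_rate)
        )
    pops_z, _ = zscore_populations(pops)
    design = LaggedDesign(pops_z)

    # amplitude (of the *unscaled* trace) at t - delay for every valid row
    p_v, edges = stimulus_distribution(traces, n_bins)
    v_rows = []
    keep_rows = []
    L = design.window
    for s, tr in enumerate(traces):
        amps = bin_amplitudes(tr)
        n = design.stim_lens[s]
        o = design.offsets[s]
        t = np.arange(L, n)
        src = t - delay_ms
        ok = src >= 0
        idx = np.clip(np.searchsorted(edges, amps[src[ok]], side="right") - 1, 0, n_bins - 1)
        v_rows.append(idx)
        keep_rows.append(o + t[ok])
    keep = np.concatenate(keep_rows)
    W = design._rows32[keep].astype(np.float64)
    v_idx = np.concatenate(v_rows)
    # p(v) restricted to the rows actually entering the MI sum
    counts = np.bincount(v_idx, minlength=n_bins)
    p_v_eff = counts / counts.sum()
    return MIProblem(
        W, v_idx, p_v_eff, edges, nl, rate_target, delay_ms, scale_ra, scale_pc
    )


# --------------------------------------------------------------------------
# mutual information and gradient
# --------------------------------------------------------------------------

def _conditional_spike_prob(problem: MIProblem, k: np.ndarray):
    x = problem.W @ k
    p = problem.nl(x)
    counts = problem.bin_counts
    sums = np.bincount(problem.v_idx, weights=p, minlength=problem.n_bins)
    with np.errstate(invalid="ignore"):
        p1v = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return x, p, p1v


def mutual_information(problem: MIProblem, filters: CorticalFilterPair | np.ndarray) -> float:
    """I(S, V) in bits for a binary spike variable.

    p(s=1|v) is the mean LNP spiking probability over time bins whose
    (delayed) stimulus amplitude falls in bin v; p(s,v) = p(s|v) p(v);
    zero-probability cells contribute zero.
    """
    k = filters.stacked if isinstance(filters, CorticalFilterPair) else np.asarray(filters)
    _, _, p1v = _conditional_spike_prob(problem, k)
    p_v = problem.p_v
    pbar = float(p_v @ p1v)
    if pbar <= 0.0 or pbar >= 1.0:
        return 0.0
    mi = 0.0
    for pv, p1 in zip(p_v, p1v):
        if pv == 0:
            continue
        for ps_v, ps in ((p1, pbar), (1.0 - p1, 1.0 - pbar)):
            if ps_v > 0:
                mi += pv * ps_v * np.log2(ps_v / ps)
    return float(mi)


def mi_gradient(problem: MIProblem, filters: CorticalFilterPair | np.ndarray) -> np.ndarray:
    """Analytic gradient of I(S, V) with respect to the 200 filter values.

    dI/dp(1|v) = p(v) log2[ p(1|v)(1-pbar) / ((1-p(1|v)) pbar) ] (the
    dependence of pbar on p(1|v) contributes zero), and
    dp(1|v)/dk = mean over bins in v of r'(x_t) w_t.
    """
    k = filters.stacked if isinstance(filters, CorticalFilterPair) else np.asarray(filters)
    x, p, p1v = _conditional_spike_prob(problem, k)
    p_v = problem.p_v
    counts = problem.bin_counts
    pbar = float(p_v @ p1v)
    if pbar <= 0.0 or pbar >= 1.0:
        return np.zeros(k.size)
    eps = 1e-300
    dmi_dp1v = p_v * (
        np.log2(np.maximum(p1v, eps) / pbar)
        - np.log2(np.maximum(1.0 - p1v, eps) / (1.0 - pbar))
    )
    # rows with p1v exactly 0 or 1 have infinite slope in theory; the
    # rectifier keeps p1v in (0,1) whenever b1 > 0, and such cells carry
    # no mass otherwise
    dmi_dp1v[(p1v <= 0) | (p1v >= 1)] = 0.0
    rprime = problem.nl.derivative(x)
    per_row = dmi_dp1v[problem.v_idx] / np.maximum(counts[problem.v_idx], 1) * rprime
    return per_row @ problem.W


def mean_rate(problem: MIProblem, k: np.ndarray) -> float:
    """Mean spiking probability per 1-ms bin under the problem's
    nonlinearity."""
    return float(np.mean(problem.nl(problem.W @ k)))


def _rate_gradient(problem: MIProblem, k: np.ndarray) -> np.ndarray:
    x = problem.W @ k
    return (problem.nl.derivative(x) @ problem.W) / problem.W.shape[0]


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------

@dataclasses.dataclass
class OptimizedFilterSet:
    """Result of one information-maximization run."""

    filters: CorticalFilterPair
    achieved_rate: float
    achieved_mi: float  # bits
    texture_id: int | None = None
    n_starts: int = 1


def _random_start(problem: MIProblem, rng: np.random.Generator) -> np.ndarray:
    """A smooth random filter scaled to satisfy the rate constraint
    approximately."""
    k = rng.standard_normal(200)
    kernel = np.exp(-0.5 * ((np.arange(-10, 11)) / 4.0) ** 2)
    kernel /= kernel.sum()
    k[:100] = np.convolve(k[:100], kernel, mode="same")
    k[100:] = np.convolve(k[100:], kernel, mode="same")
    x = problem.W @ k
    sd = x.std() or 1.0
    k /= sd
    # bisect a scale so the mean rate matches the target
    lo, hi = 1e-3, 1e3
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if mean_rate(problem, k * mid) < problem.rate_target:
            lo = mid
        else:
            hi = mid
    return k * np.sqrt(lo * hi)


def optimize_filters(
    problem: MIProblem,
    init: np.ndarray | CorticalFilterPair | None = None,
    seed: int | np.random.Generator = 0,
    n_starts: int = 10,
    maxiter: int = 300,
    texture_id: int | None = None,
) -> OptimizedFilterSet:
    """Maximize I(S, V) subject to the mean-rate equality constraint.

    Runs SLSQP (gradient-based, equality-constrained) from ``n_starts``
    random smooth initializations (plus ``init`` if given) and keeps the
    best feasible solution; deterministic for a fixed seed.  The result
    never has lower MI than the best initialization.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(init.stacked if isinstance(init, CorticalFilterPair) else np.asarray(init, float))
    starts.extend(_random_start(problem, rng) for _ in range(n_starts))

    best_k, best_mi = None, -np.inf
    constraint = {
        "type": "eq",
        "fun": lambda k: mean_rate(problem, k) - problem.rate_target,
        "jac": lambda k: _rate_gradient(problem, k),
    }
    for k0 in starts:
        res = scipy.optimize.minimize(
            lambda k: -mutual_information(problem, k),
            k0,
            jac=lambda k: -mi_gradient(problem, k),
            constraints=[constraint],
            method="SLSQP",
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        for cand in (res.x, k0):
            if abs(mean_rate(problem, cand) - problem.rate_target) > 0.1 * problem.rate_target:
                continue
            mi = mutual_information(problem, cand)
            if mi > best_mi:
                best_mi, best_k = mi, cand.copy()
    if best_k is None:
        raise RuntimeError("no feasible solution found for the rate constraint")
    return OptimizedFilterSet(
        CorticalFilterPair.from_stacked(best_k),
        mean_rate(problem, best_k),
        best_mi,
        texture_id,
        len(starts),
    )


# --------------------------------------------------------------------------
# texture-set driver
# --------------------------------------------------------------------------

def optimize_texture_set(
    textures: Sequence[Sequence[StimulusTrace]],
    afferent_models: Sequence[AfferentModel],
    nl: Nonlinearity | None = None,
    rate_target: float = 0.05,
    target_ra_rate_hz: float = 80.0,
    target_pc_rate_hz: float = 120.0,
    seed: int | np.random.Generator = 0,
    n_starts: int = 10,
    maxiter: int = 300,
    min_rate_hz: float = 20.0,
):
    """Optimize filters for each texture individually.

    For every texture (a set of vibration traces) the afferent input is
    scaled so mean RA/PC population rates match the targets, textures
    whose rates stay below ``min_rate_hz`` for either class are dropped,
    and an information-maximizing filter pair is fit per texture.
    Returns (results, summary DataFrame) where the summary holds per
    texture the achieved MI and rate, the RA/PC magnitude ratio, widths
    and excitation indices of the optimized filters.
    """
    import pandas as pd

    from . import metrics

    nl = nl or Nonlinearity(0.01, 0.05)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    results = []
    rows = []
    for ti, traces in enumerate(textures):
        scale_ra, scale_pc = calibrate_scaling(
            traces, afferent_models, target_ra_rate_hz, target_pc_rate_hz
        )
        r_ra, _ = mean_class_rates(traces, afferent_models, scale_ra=scale_ra)
        _, r_pc = mean_class_rates(traces, afferent_models, scale_pc=scale_pc)
        if not texture_inclusion_filter(r_ra, r_pc, min_rate_hz):
            continue
        problem = build_mi_problem(
            traces, afferent_models, nl, rate_target, scale_ra=scale_ra, scale_pc=scale_pc
        )
        res = optimize_filters(
            problem, seed=rng, n_starts=n_starts, maxiter=maxiter, texture_id=ti
        )
        results.append(res)
        k = res.filters
        rows.append(
            {
                "texture_id": ti,
                "mi_bits": res.achieved_mi,
                "rate": res.achieved_rate,
                "ra_rate_hz": r_ra,
                "pc_rate_hz": r_pc,
                "magnitude_ra": metrics.filter_magnitude(k.k_ra),
                "magnitude_pc": metrics.filter_magnitude(k.k_pc),
                "magnitude_ratio": metrics.filter_magnitude(k.k_ra)
                / max(metrics.filter_magnitude(k.k_pc), 1e-12),
                "width_ra_ms": metrics.filter_width(k.k_ra),
                "width_pc_ms": metrics.filter_width(k.k_pc),
                "ei_ra": metrics.excitation_index(k.k_ra) if np.any(k.k_ra) else np.nan,
                "ei_pc": metrics.excitation_index(k.k_pc) if np.any(k.k_pc) else np.nan,
            }
        )
    return results, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# texture bookkeeping
# --------------------------------------------------------------------------

def texture_inclusion_filter(ra_rate_hz: float, pc_rate_hz: float, min_rate_hz: float = 20.0) -> bool:
    """Keep a texture only if both afferent classes respond at or above
    ``min_rate_hz`` (textures that barely drive one class cannot
    constrain its filter)."""
    if ra_rate_hz < 0 or pc_rate_hz < 0:
        raise ValueError("rates must be non-negative")
    return ra_rate_hz >= min_rate_hz and pc_rate_hz >= min_rate_hz


def mean_class_rates(
    traces: Sequence[StimulusTrace],
    afferent_models: Sequence[AfferentModel],
    scale_ra: float = 1.0,
    scale_pc: float = 1.0,
    dt_ms: float = 0.05,
) -> tuple[float, float]:
    """Mean simulated RA and PC population rates over a texture's traces."""
    ra_models = [m for m in afferent_models if m.afferent_class == "RA"]
    pc_models = [m for m in afferent_models if m.afferent_class == "PC"]
    ra, pc = [], []
    for tr in traces:
        pr = population_rate(
            ra_models, StimulusTrace(tr.samples * scale_ra, tr.sample_rate), dt_ms, require_both=False
        )
        ra.append(pr.ra_rate.mean())
        pr = population_rate(
            pc_models, StimulusTrace(tr.samples * scale_pc, tr.sample_rate), dt_ms, require_both=False
        )
        pc.append(pr.pc_rate.mean())
    return float(np.mean(ra)), float(np.mean(pc))


def calibrate_scaling(
    traces: Sequence[StimulusTrace],
    afferent_models: Sequence[AfferentModel],
    target_ra_rate_hz: float,
    target_pc_rate_hz: float,
    tol: float = 0.05,
    scale_bounds: tuple[float, float] = (1e-3, 1e3),
    dt_ms: float = 0.05,
) -> tuple[float, float]:
    """Global per-class trace scalings that match mean simulated
    population rates to targets (within ``tol``, by bisection).

    Mimics the adjustment for vibration-amplitude decay between the
    measurement point and the receptor sheet.
    """
    if target_ra_rate_hz <= 0 or target_pc_rate_hz <= 0:
        raise ValueError("targets must be positive")

    def solve(which: str, target: float) -> float:
        lo, hi = scale_bounds

        def rate(scale: float) -> float:
            r_ra, r_pc = mean_class_rates(
                traces,
                afferent_models,
                scale_ra=scale if which == "RA" else 0.0,
                scale_pc=scale if which == "PC" else 0.0,
                dt_ms=dt_ms,
            )
            return r_ra if which == "RA" else r_pc

        if rate(hi) < target * (1 - tol):
            raise ValueError(f"{which} target rate unreachable within scale bounds")
        for _ in range(60):
            mid = np.sqrt(lo * hi)
            r = rate(mid)
            if abs(r - target) <= tol * target:
                return mid
            if r < target:
                lo = mid
            else:
                hi = mid
        return np.sqrt(lo * hi)

    return solve("RA", target_ra_rate_hz), solve("PC", target_pc_rate_hz)
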