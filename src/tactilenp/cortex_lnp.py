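"""Linear-nonlinear-Poisson (LNP) model of S1 cortical neurons.

A cortical neuron's probability of spiking in a 1-ms bin is

    p(s_t) = r( k_RA . s_RA,t  +  k_PC . s_PC,t )

where ``s_RA,t`` and ``s_PC,t`` are the (z-scored) RA and PC population
rates over the 100 ms preceding ``t`` and ``r`` is a piecewise-linear
rectifier r(x) = b1 for x < 0, b1 + b2*x clipped at 1 otherwise.

Filters are estimated by reverse correlation with a ridge correction for
input autocorrelation:

    k = (S^T S + a I)^-1  S^T s_C

with ``S`` the lagged design matrix of concatenated RA and PC history
windows (200 columns) and ``s_C`` the binary spike vector.  Lag-axis
convention, fixed repo-wide: filter index ``j`` (equivalently design
column ``j``) multiplies the population rate at ``t - (j+1)`` ms, i.e.
index 0 is the most recent past bin.

Whether a neuron receives RA input, PC input, or both is decided per
class by a noise-whitened filter statistic calibrated against a
parametric bootstrap of the "other class alone" hypothesis, which
accounts for both estimation noise and the systematic cross-class
spill-over of linear estimation applied to a rectified model; see
``classify_input``.  Circular-shift surrogates (stimulus locking
broken, spike statistics preserved) are also available on the design
(``LaggedDesign.null_filter_magnitudes``).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.optimize import lsq_linear

from .periphery import PopulationResponse

WINDOW_MS = 100
N_QUANTILE_BINS = 50  # drive bins used when fitting the nonlinearity


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclasses.dataclass
class CorticalFilterPair:
    """RA and PC temporal filters, 100 coefficients each at 1-ms bins.

    ``k_ra[j]`` weights the RA population rate ``j+1`` ms before the
    response bin (index 0 = most recent past bin).
    """

    k_ra: np.ndarray
    k_pc: np.ndarray
    bin_ms: float = 1.0
    window_ms: int = WINDOW_MS

    def __post_init__(self) -> None:
        self.k_ra = np.asarray(self.k_ra, dtype=np.float64)
        self.k_pc = np.asarray(self.k_pc, dtype=np.float64)
        n = int(round(self.window_ms / self.bin_ms))
        if self.k_ra.shape != (n,) or self.k_pc.shape != (n,):
            raise ValueError(f"filters must have exactly {n} coefficients")
        if not (np.all(np.isfinite(self.k_ra)) and np.all(np.isfinite(self.k_pc))):
            raise ValueError("filter values must be finite")

    @property
    def stacked(self) -> np.ndarray:
        """Concatenated [k_ra, k_pc] vector (length 200)."""
        return np.concatenate([self.k_ra, self.k_pc])

    @classmethod
    def from_stacked(cls, k: np.ndarray, window_ms: int = WINDOW_MS) -> "CorticalFilterPair":
        k = np.asarray(k, dtype=np.float64)
        n = k.size // 2
        return cls(k[:n], k[n:], window_ms=n)

    def save(self, path) -> None:
        lags = np.arange(1, self.k_ra.size + 1) * self.bin_ms
        arr = np.column_stack([lags, self.k_ra, self.k_pc])
        np.savetxt(path, arr, header="lag_ms\tk_ra\tk_pc", delimiter="\t")

    @classmethod
    def load(cls, path) -> "CorticalFilterPair":
        arr = np.loadtxt(path)
        return cls(arr[:, 1], arr[:, 2], window_ms=arr.shape[0])


@dataclasses.dataclass
class Nonlinearity:
    """Piecewise-linear rectifier: baseline ``b1`` (probability per 1-ms
    bin), gain ``b2`` (probability per unit linear drive)."""

    b1: float
    b2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.b1 <= 1.0:
            raise ValueError("b1 must lie in [0, 1]")
        if self.b2 < 0:
            raise ValueError("b2 must be non-negative")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return np.clip(self.b1 + self.b2 * np.maximum(x, 0.0), self.b1, 1.0)

    def derivative(self, x: np.ndarray) -> np.ndarray:
        """Almost-everywhere derivative dr/dx; the sub-gradient at the
        x=0 kink is taken from the right branch."""
        x = np.asarray(x, dtype=np.float64)
        inside = (x >= 0.0) & (self.b1 + self.b2 * x < 1.0)
        return np.where(inside, self.b2, 0.0)


@dataclasses.dataclass
class CorticalSpikeData:
    """Binary 1-ms-binned spike trains, one array per trial.

    ``stimulus_id[i]`` indexes the stimulus (population response) that
    trial ``i`` was recorded under; repeats of a frozen stimulus share
    an id.
    """

    trials: list[np.ndarray]
    stimulus_id: list[int] | None = None

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t) for t in self.trials]
        for t in self.trials:
            if t.ndim != 1 or not np.isin(t, (0, 1)).all():
                raise ValueError("trials must be 1-D binary vectors")
        self.trials = [t.astype(np.uint8) for t in self.trials]
        if self.stimulus_id is None:
            self.stimulus_id = [0] * len(self.trials)
        if len(self.stimulus_id) != len(self.trials):
            raise ValueError("stimulus_id must align with trials")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_repeats(self) -> int:
        ids, counts = np.unique(self.stimulus_id, return_counts=True)
        return int(counts.min()) if ids.size else 0

    def total_spikes(self) -> int:
        return int(sum(int(t.sum()) for t in self.trials))


@dataclasses.dataclass
class RidgeConfig:
    """Ridge-regression settings for reverse correlation."""

    a: float = 0.0
    design_window_ms: int = WINDOW_MS

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("regularization weight a must be >= 0")


# --------------------------------------------------------------------------
# lagged design matrix (shared across neurons and null surrogates)
# --------------------------------------------------------------------------

class LaggedDesign:
    """Lagged design matrix over a set of z-scored population responses.

    Rows correspond to response bins ``t`` with a complete 100-ms
    history (the first 100 ms of every stimulus are excluded); columns
    0..99 hold the RA rate at lags 1..100 ms, columns 100..199 the PC
    rate.  The heavy pieces (per-stimulus S^T S blocks and a float32
    copy of all rows for surrogate resampling) are computed once and
    shared across neurons.
    """

    def __init__(self, pops: Sequence[PopulationResponse], window_ms: int = WINDOW_MS):
        if not pops:
            raise ValueError("need at least one population response")
        for p in pops:
            if not p.zscored:
                raise ValueError("population responses must be z-scored")
        self.window = int(window_ms)
        L = self.window
        self.n_stimuli = len(pops)
        self.stim_lens = np.array([p.n_bins for p in pops], dtype=np.int64)
        if np.any(self.stim_lens <= L):
            raise ValueError(f"every stimulus must be longer than {L} ms")
        self.offsets = np.concatenate([[0], np.cumsum(self.stim_lens)])
        self.n_rows_total = int(self.offsets[-1])

        # float32 row bank for surrogate shifts; invalid rows (incomplete
        # history) are all-zero
        self._rows32 = np.zeros((self.n_rows_total, 2 * L), dtype=np.float32)
        self._sts_blocks = []
        self._g_ra = np.concatenate([p.ra_rate for p in pops])
        self._g_pc = np.concatenate([p.pc_rate for p in pops])
        self.valid = np.ones(self.n_rows_total, dtype=bool)
        self.row_stim = np.empty(self.n_rows_total, dtype=np.int32)
        for s, p in enumerate(pops):
            block = self._stim_design(p)
            o = self.offsets[s]
            self._rows32[o + L : o + self.stim_lens[s]] = block.astype(np.float32)
            self._sts_blocks.append(block.T @ block)
            self.valid[o : o + L] = False
            self.row_stim[o : o + self.stim_lens[s]] = s
        self._chol_cache: dict[tuple[float, tuple[int, ...]], object] = {}

    def _stim_design(self, p: PopulationResponse) -> np.ndarray:
        L = self.window
        cols = []
        for g in (p.ra_rate, p.pc_rate):
            w = np.lib.stride_tricks.sliding_window_view(g, L)  # w[i] = g[i:i+L]
            # row for response bin t uses g[t-L:t] reversed -> w[t-L][::-1]
            cols.append(w[:-1][:, ::-1])
        return np.concatenate(cols, axis=1)

    # -- per-neuron quantities ---------------------------------------------

    def _check_spikes(self, spikes: CorticalSpikeData) -> None:
        if spikes.n_trials == 0:
            raise ValueError("spike data contains no trials")
        for tr, sid in zip(spikes.trials, spikes.stimulus_id):
            if not 0 <= sid < self.n_stimuli:
                raise ValueError(f"stimulus_id {sid} out of range")
            if tr.size != self.stim_lens[sid]:
                raise ValueError("trial length does not match its stimulus")

    def repeat_counts(self, spikes: CorticalSpikeData) -> np.ndarray:
        counts = np.zeros(self.n_stimuli, dtype=np.int64)
        for sid in spikes.stimulus_id:
            counts[sid] += 1
        return counts

    def summed_counts(self, spikes: CorticalSpikeData) -> np.ndarray:
        """Spike counts summed over repeats, on the design timeline."""
        c = np.zeros(self.n_rows_total)
        for tr, sid in zip(spikes.trials, spikes.stimulus_id):
            o = self.offsets[sid]
            c[o : o + tr.size] += tr
        return c

    def sts(self, repeat_counts: np.ndarray) -> np.ndarray:
        A = np.zeros_like(self._sts_blocks[0])
        for n_s, block in zip(repeat_counts, self._sts_blocks):
            if n_s:
                A += n_s * block
        return A

    def st_y(self, spikes: CorticalSpikeData) -> np.ndarray:
        """S^T s_C summed over trials (exact, float64)."""
        self._check_spikes(spikes)
        L = self.window
        c = self.summed_counts(spikes)
        # zero out bins without complete history
        for s in range(self.n_stimuli):
            o = self.offsets[s]
            c[o : o + L] = 0.0
        idx = np.nonzero(c)[0]
        w = c[idx]
        sty = np.empty(2 * L)
        for j in range(L):
            sty[j] = self._g_ra[idx - 1 - j] @ w
            sty[L + j] = self._g_pc[idx - 1 - j] @ w
        return sty

    def _factor(self, a: float, repeat_counts: np.ndarray):
        key = (float(a), tuple(repeat_counts.tolist()))
        if key not in self._chol_cache:
            A = self.sts(repeat_counts)
            A[np.diag_indices_from(A)] += a
            try:
                self._chol_cache[key] = ("chol", scipy.linalg.cho_factor(A))
            except scipy.linalg.LinAlgError:
                warnings.warn(
                    "S^T S + aI is singular; falling back to pseudoinverse"
                )
                self._chol_cache[key] = ("pinv", np.linalg.pinv(A))
        return self._chol_cache[key]

    def solve(self, a: float, repeat_counts: np.ndarray, sty: np.ndarray) -> np.ndarray:
        kind, fac = self._factor(a, repeat_counts)
        if kind == "chol":
            return scipy.linalg.cho_solve(fac, sty.T).T
        return (fac @ sty.T).T

    def st_p(self, p_unique: np.ndarray, repeat_counts: np.ndarray) -> np.ndarray:
        """S^T applied to a dense per-bin probability trace on the design
        timeline (weighted by per-stimulus repeat counts, invalid bins
        excluded).  Used for noise-free regressions of model-predicted
        probabilities."""
        w = np.where(self.valid, p_unique, 0.0) * repeat_counts[self.row_stim]
        return (w.astype(np.float32) @ self._rows32).astype(np.float64)

    # -- circular-shift surrogates -----------------------------------------

    def trial_timeline(self, spikes: CorticalSpikeData) -> tuple[np.ndarray, np.ndarray, int]:
        """Global spike positions on the concatenated trial timeline and
        the map from global bins to design rows."""
        self._check_spikes(spikes)
        lens = [self.stim_lens[sid] for sid in spikes.stimulus_id]
        total = int(np.sum(lens))
        row_map = np.empty(total, dtype=np.int64)
        spike_pos = []
        pos = 0
        for tr, sid in zip(spikes.trials, spikes.stimulus_id):
            o = self.offsets[sid]
            row_map[pos : pos + tr.size] = np.arange(o, o + tr.size)
            spike_pos.append(pos + np.nonzero(tr)[0])
            pos += tr.size
        return np.concatenate(spike_pos), row_map, total

    def null_filter_coefficients(
        self,
        spikes: CorticalSpikeData,
        a: float,
        n_null: int,
        seed: int | np.random.Generator,
        min_shift_ms: int = 200,
    ) -> np.ndarray:
        """Filter coefficient vectors re-estimated after circular shifts
        of the whole spike timeline (stimulus locking broken, spike
        statistics preserved).

        Returns an (n_null, 200) array.  Shifts are drawn uniformly from
        [min_shift, T - min_shift].
        """
        spike_pos, row_map, total = self.trial_timeline(spikes)
        if total < 2 * min_shift_ms + 1:
            raise ValueError("data too short for circular-shift surrogates")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        shifts = rng.integers(min_shift_ms, total - min_shift_ms, size=n_null)
        # B[i] = sum over spikes of the design row at the shifted position
        rows = row_map[(spike_pos[None, :] + shifts[:, None]) % total].ravel()
        cols = np.repeat(np.arange(n_null), spike_pos.size)
        Y = scipy.sparse.csr_matrix(
            (np.ones(rows.size, dtype=np.float32), (cols, rows)),
            shape=(n_null, self.n_rows_total),
        )
        B = np.asarray(Y @ self._rows32, dtype=np.float64)  # (n_null, 200)
        return self.solve(a, self.repeat_counts(spikes), B)

    def null_filter_magnitudes(
        self,
        spikes: CorticalSpikeData,
        a: float,
        n_null: int,
        seed: int | np.random.Generator,
        min_shift_ms: int = 200,
    ) -> np.ndarray:
        """Filter magnitudes (sum |k| per class) of circular-shift
        surrogates; an (n_null, 2) array of [RA, PC] magnitudes."""
        K = self.null_filter_coefficients(spikes, a, n_null, seed, min_shift_ms)
        L = self.window
        return np.column_stack(
            [np.abs(K[:, :L]).sum(axis=1), np.abs(K[:, L:]).sum(axis=1)]
        )

    def estimator_bank(
        self, a: float, repeat_counts: np.ndarray, block: slice | None = None
    ) -> np.ndarray:
        """The matrix G = S (S^T S + aI)^-1 (float32, rows aligned with
        the design timeline), cached per (a, repeat profile, block).

        The ridge estimate for any summed-count vector y is simply
        y @ G, which turns surrogate re-estimation into one sparse
        matrix product with no per-surrogate solves.  ``block``
        restricts (and caches) a contiguous column range.
        """
        bkey = (block.start, block.stop) if block is not None else None
        key = ("bank", float(a), tuple(repeat_counts.tolist()), bkey)
        if key not in self._chol_cache:
            full_key = ("bank", float(a), tuple(repeat_counts.tolist()), None)
            if full_key not in self._chol_cache:
                A = self.sts(repeat_counts)
                A[np.diag_indices_from(A)] += a
                A_inv = np.linalg.inv(A)
                self._chol_cache[full_key] = self._rows32 @ A_inv.astype(np.float32)
            if bkey is None:
                return self._chol_cache[full_key]
            self._chol_cache[key] = np.ascontiguousarray(
                self._chol_cache[full_key][:, block]
            )
        return self._chol_cache[key]

    def bootstrap_filter_coefficients(
        self,
        p_hat: np.ndarray,
        repeat_counts: np.ndarray,
        a: float,
        n_draws: int,
        seed: int | np.random.Generator,
        block: slice | None = None,
    ) -> np.ndarray:
        """Filter coefficient vectors re-estimated from surrogate spike
        counts drawn from a model's predicted probabilities.

        Per design bin the repeat-summed spike count is Binomial
        (n_repeats, p_hat); it is sampled here as a Poisson process with
        the same mean (counts are small per bin, and the Poisson
        variance is a few percent above the Binomial's — conservative).
        Sampling exploits sparsity: total counts first, positions by
        inverse-CDF, so each draw costs only its spikes.  ``block``
        restricts the returned coefficients (and the work) to a column
        range of the design.

        Returns an (n_draws, n_coefficients) array.
        """
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        G = self.estimator_bank(a, repeat_counts, block)
        lam = np.where(self.valid, p_hat, 0.0) * repeat_counts[self.row_stim]
        cum = np.cumsum(lam)
        total = cum[-1]
        if total <= 0:
            return np.zeros((n_draws, G.shape[1]))
        n_spikes = rng.poisson(total, size=n_draws)
        pos = np.searchsorted(cum, rng.random(int(n_spikes.sum())) * total)
        cols = np.repeat(np.arange(n_draws), n_spikes)
        Y = scipy.sparse.csr_matrix(
            (np.ones(pos.size, dtype=np.float32), (cols, pos)),
            shape=(n_draws, self.n_rows_total),
        )
        return np.asarray(Y @ G, dtype=np.float64)


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

def lnp_drive(filters: CorticalFilterPair, pop: PopulationResponse) -> np.ndarray:
    """Linear drive x_t = k_RA . s_RA,window(t) + k_PC . s_PC,window(t).

    The first ``window`` bins, which lack a complete history, are NaN.
    """
    if not pop.zscored:
        raise ValueError("population response must be z-scored")
    L = filters.k_ra.size
    if pop.n_bins < L:
        raise ValueError("population response shorter than the filter window")
    x = np.full(pop.n_bins, np.nan)
    c = np.convolve(pop.ra_rate, filters.k_ra) + np.convolve(pop.pc_rate, filters.k_pc)
    # c[m] = sum_j k[j] * s[m-j]; the drive at t uses s up to t-1: x_t = c[t-1]
    x[L:] = c[L - 1 : pop.n_bins - 1]
    return x


def lnp_predict(
    filters: CorticalFilterPair, nl: Nonlinearity, pop: PopulationResponse
) -> np.ndarray:
    """Per-bin spiking probability of the LNP model.

    Bins without a complete 100-ms history are emitted at the baseline
    ``b1``.  Output always lies in [0, 1].
    """
    x = lnp_drive(filters, pop)
    p = np.full(x.size, nl.b1)
    valid = ~np.isnan(x)
    p[valid] = nl(x[valid])
    return p


def sample_spikes(
    probabilities: np.ndarray,
    n_repeats: int,
    seed: int | np.random.Generator,
    stimulus_id: int = 0,
) -> CorticalSpikeData:
    """Draw Bernoulli spike trains, one independent draw per bin per repeat."""
    p = np.asarray(probabilities, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    trials = [(rng.random(p.size) < p).astype(np.uint8) for _ in range(n_repeats)]
    return CorticalSpikeData(trials, [stimulus_id] * n_repeats)


# --------------------------------------------------------------------------
# estimation
# --------------------------------------------------------------------------

def _as_pop_list(pop) -> list[PopulationResponse]:
    return [pop] if isinstance(pop, PopulationResponse) else list(pop)


def estimate_filters(
    pop,
    spikes: CorticalSpikeData,
    cfg: RidgeConfig,
    design: LaggedDesign | None = None,
) -> CorticalFilterPair:
    """Ridge-corrected reverse-correlation estimate of the RA/PC filters.

    Solves k = (S^T S + a I)^-1 S^T s_C over all trials, excluding the
    first 100 ms of each.  With ``a = 0`` this is ordinary least squares
    (pseudoinverse if the design is rank-deficient).
    """
    pops = _as_pop_list(pop)
    if design is None:
        design = LaggedDesign(pops, cfg.design_window_ms)
    if spikes.n_trials == 0:
        raise ValueError("spike data contains no trials")
    sty = design.st_y(spikes)
    k = design.solve(cfg.a, design.repeat_counts(spikes), sty)
    return CorticalFilterPair.from_stacked(k, window_ms=design.window)


def fit_nonlinearity(linear_drive: np.ndarray, spikes) -> Nonlinearity:
    """Fit the piecewise-linear rectifier to observed spike probability.

    ``linear_drive`` and ``spikes`` are aligned 1-D arrays pooled over
    trials (binary spikes).  The drive is split into 50 quantile bins;
    (b1, b2) are fit by least squares of r(x) = b1 + b2*[x]+ to the
    per-bin empirical spike probability, constrained to b1 in [0, 1] and
    b2 >= 0.
    """
    if isinstance(spikes, CorticalSpikeData):
        spikes = np.concatenate(spikes.trials)
    x = np.asarray(linear_drive, dtype=np.float64)
    y = np.asarray(spikes, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("drive and spikes must be aligned")
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no finite drive values")
    if y.sum() == 0:
        return Nonlinearity(0.0, 0.0)
    if np.ptp(x) == 0:
        return Nonlinearity(float(np.clip(y.mean(), 0, 1)), 0.0)
    edges = np.quantile(x, np.linspace(0, 1, N_QUANTILE_BINS + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1)
    keep = counts > 0
    p_emp = np.bincount(idx, weights=y, minlength=edges.size - 1)[keep] / counts[keep]
    # regressor: per-bin mean of [x]+ (the model's expected probability in
    # a bin is b1 + b2 * E[[x]+], which matters for the bin straddling 0)
    xpos_mean = (
        np.bincount(idx, weights=np.maximum(x, 0.0), minlength=edges.size - 1)[keep]
        / counts[keep]
    )
    wts = np.sqrt(counts[keep])
    A = np.column_stack([np.ones(xpos_mean.size), xpos_mean]) * wts[:, None]
    res = lsq_linear(A, p_emp * wts, bounds=([0.0, 0.0], [1.0, np.inf]))
    b1, b2 = res.x
    return Nonlinearity(float(min(b1, 1.0)), float(b2))


def fit_lnp(
    pop,
    spikes: CorticalSpikeData,
    cfg: RidgeConfig,
    design: LaggedDesign | None = None,
) -> tuple[CorticalFilterPair, Nonlinearity]:
    """Estimate filters, then fit the nonlinearity on the resulting drive."""
    pops = _as_pop_list(pop)
    if design is None:
        design = LaggedDesign(pops, cfg.design_window_ms)
    filters = estimate_filters(pops, spikes, cfg, design=design)
    drives, spk = pooled_drive(filters, pops, spikes)
    nl = fit_nonlinearity(drives, spk)
    return filters, nl


def pooled_drive(
    filters: CorticalFilterPair, pops, spikes: CorticalSpikeData
) -> tuple[np.ndarray, np.ndarray]:
    """Linear drive and spikes pooled over trials (valid bins only)."""
    pops = _as_pop_list(pops)
    per_stim = {}
    xs, ys = [], []
    L = filters.k_ra.size
    for tr, sid in zip(spikes.trials, spikes.stimulus_id):
        if sid not in per_stim:
            per_stim[sid] = lnp_drive(filters, pops[sid])
        xs.append(per_stim[sid][L:])
        ys.append(tr[L:])
    return np.concatenate(xs), np.concatenate(ys)


# --------------------------------------------------------------------------
# input-class decision
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ClassificationResult:
    label: str  # both | RA_only | PC_only | none
    p_ra: float
    p_pc: float
    magnitude_ra: float
    magnitude_pc: float
    stat_ra: float
    stat_pc: float
    stat_threshold_ra: float
    stat_threshold_pc: float
    leak_ra: float
    leak_pc: float
    filters: CorticalFilterPair


def _single_class_hypothesis(
    filters: CorticalFilterPair,
    spikes: CorticalSpikeData,
    cfg: RidgeConfig,
    design: LaggedDesign,
    keep: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted probabilities and expected coefficient vector under the
    hypothesis that the neuron receives input from ``keep`` alone.

    Linear estimation of a rectified model is systematically biased: the
    best linear fit of r(x) recruits any input that co-varies with
    functions of the drive (both populations share the stimulus
    envelope), so a single-input neuron shows a small systematic
    "spill-over" weight in the class it does not receive.  The
    hypothesis is built from the *joint* fit: zero the other class's
    half of the estimated filters and refit the rectifier on the
    remaining drive.  (A single-class refit would absorb part of the
    other class's real signal for genuinely dual-input neurons and
    overstate the spill-over.)  Returns the per-bin probability trace on
    the design timeline and the expected full-design regression
    coefficients (the spill-over lives in the other class's block).
    """
    L = design.window
    k = filters.stacked.copy()
    if keep == "RA":
        k[L:] = 0.0
    else:
        k[:L] = 0.0
    counts = design.repeat_counts(spikes)
    x = design._rows32 @ k.astype(np.float32)
    y = design.summed_counts(spikes) / counts[design.row_stim]
    nl = fit_nonlinearity(x[design.valid], y[design.valid])
    p = nl(x)
    k_expected = design.solve(cfg.a, counts, design.st_p(p, counts))
    return p, k_expected


def classify_input(
    pop,
    spikes: CorticalSpikeData,
    cfg: RidgeConfig,
    n_null: int = 500,
    alpha: float = 0.02,
    seed: int | np.random.Generator = 0,
    design: LaggedDesign | None = None,
    filters: CorticalFilterPair | None = None,
    cov_shrinkage: float = 0.1,
) -> ClassificationResult:
    """Decide whether a neuron receives RA input, PC input, or both.

    Per class the test asks whether the estimated filters differ from
    what the *other* class alone would produce.  The null is a
    parametric bootstrap: surrogate spike counts are drawn from the
    single-class hypothesis's predicted probabilities
    (``_single_class_hypothesis``) and the filters re-estimated, which
    bakes in both the estimation noise and the systematic cross-class
    spill-over of linear estimation applied to a rectified model.  The
    statistic is a noise-whitened (Mahalanobis) norm of the class's
    coefficients under the surrogate covariance — whitening matters
    because reverse-correlation noise is strongly correlated across
    lags, and a plain sum of absolute values buries a narrow filter
    under 100 lags of correlated noise.  The surrogate set is split in
    half (covariance half / quantile half) so null statistics are
    scored out-of-sample.

    A class contributes when its statistic exceeds the null's
    (1 - alpha) quantile; ``alpha`` defaults to 0.02 per class, placing
    dual false positives on single-input neurons in the low percent
    range.  Stimulus-independent spiking yields near-constant
    hypothesis probabilities, so the same null also calibrates the
    "none" decision.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    pops = _as_pop_list(pop)
    if design is None:
        design = LaggedDesign(pops, cfg.design_window_ms)
    # circular-shift feasibility guard: surrogate-based testing needs
    # appreciably more data than the 100-ms window itself
    _, _, total = design.trial_timeline(spikes)
    if total < 2 * 200 + 1:
        raise ValueError("data too short for surrogate-based classification")
    if filters is None:
        filters = estimate_filters(pops, spikes, cfg, design=design)
    L = design.window
    k_obs = filters.stacked
    counts = design.repeat_counts(spikes)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    stats, thresholds, pvals, leak_mag = {}, {}, {}, {}
    for name, keep_other, block in (
        ("ra", "PC", slice(0, L)),
        ("pc", "RA", slice(L, 2 * L)),
    ):
        p_h0, k_h0 = _single_class_hypothesis(filters, spikes, cfg, design, keep_other)
        K = design.bootstrap_filter_coefficients(
            p_h0, counts, cfg.a, n_null, rng, block=block
        )
        # fold swap: each half's covariance whitens the other half's
        # draws (and the observed filters), so every null statistic is
        # scored out-of-sample — in-sample Mahalanobis norms are biased
        # low and would make the test anti-conservative
        t_obs_folds, t_null_all = [], []
        half = n_null // 2
        halves = (K[:half], K[half:])
        for cov_half, score_half in ((halves[0], halves[1]), (halves[1], halves[0])):
            mu = cov_half.mean(axis=0)
            cov = np.cov(cov_half.T)
            cov[np.diag_indices_from(cov)] += cov_shrinkage * np.trace(cov) / L
            c_inv = np.linalg.inv(cov)
            d_obs = k_obs[block] - mu
            t_obs_folds.append(float(d_obs @ c_inv @ d_obs))
            D = score_half - mu[None, :]
            t_null_all.append(np.einsum("ij,jk,ik->i", D, c_inv, D))
        # p-value pooled over folds (each fold's observed statistic is
        # exchangeable with that fold's null draws under H0)
        exceed = sum(
            int(np.sum(tn >= tf)) for tn, tf in zip(t_null_all, t_obs_folds)
        )
        pvals[name] = float((1 + exceed) / (K.shape[0] + 1))
        stats[name] = float(np.mean(t_obs_folds))
        thresholds[name] = float(np.quantile(np.concatenate(t_null_all), 1.0 - alpha))
        leak_mag[name] = float(np.abs(k_h0[block]).sum())

    has_ra = pvals["ra"] <= alpha
    has_pc = pvals["pc"] <= alpha
    label = {
        (True, True): "both",
        (True, False): "RA_only",
        (False, True): "PC_only",
        (False, False): "none",
    }[(has_ra, has_pc)]
    return ClassificationResult(
        label,
        pvals["ra"],
        pvals["pc"],
        float(np.abs(filters.k_ra).sum()),
        float(np.abs(filters.k_pc).sum()),
        stats["ra"],
        stats["pc"],
        thresholds["ra"],
        thresholds["pc"],
        leak_mag["ra"],
        leak_mag["pc"],
        filters,
    )


def refit_single_class(
    pop,
    spikes: CorticalSpikeData,
    cfg: RidgeConfig,
    keep: str,
    design: LaggedDesign | None = None,
) -> tuple[CorticalFilterPair, Nonlinearity]:
    """Refit filters and nonlinearity using only one afferent class.

    The design matrix is restricted to the kept class's 100 columns; the
    other class's filter is exactly zero in the result.
    """
    if keep not in ("RA", "PC"):
        raise ValueError("keep must be 'RA' or 'PC'")
    pops = _as_pop_list(pop)
    if design is None:
        design = LaggedDesign(pops, cfg.design_window_ms)
    L = design.window
    sl = slice(0, L) if keep == "RA" else slice(L, 2 * L)
    counts = design.repeat_counts(spikes)
    A = design.sts(counts)[sl, sl].copy()
    A[np.diag_indices_from(A)] += cfg.a
    sty = design.st_y(spikes)[sl]
    try:
        k_half = scipy.linalg.cho_solve(scipy.linalg.cho_factor(A), sty)
    except scipy.linalg.LinAlgError:
        warnings.warn("singular single-class design; using pseudoinverse")
        k_half = np.linalg.pinv(A) @ sty
    zero = np.zeros(L)
    filters = (
        CorticalFilterPair(k_half, zero, window_ms=L)
        if keep == "RA"
        else CorticalFilterPair(zero, k_half, window_ms=L)
    )
    drive, spk = pooled_drive(filters, pops, spikes)
    nl = fit_nonlinearity(drive, spk)
    return filters, nl


# --------------------------------------------------------------------------
# regularization selection
# --------------------------------------------------------------------------

def select_ridge_penalty(
    design: LaggedDesign,
    spikes: CorticalSpikeData,
    grid: Sequence[float] | None = None,
    n_folds: int = 5,
    seed: int | np.random.Generator = 0,
) -> float:
    """Choose the ridge weight by K-fold cross-validated prediction.

    Stimuli are split into folds; for each candidate ``a`` the filters
    are estimated on the training folds and scored by the Pearson
    correlation between the linear prediction and the repeat-summed
    spike counts on the held-out fold.  Returns the best ``a``.
    """
    if grid is None:
        scale = float(np.mean(np.diag(design.sts(design.repeat_counts(spikes)))))
        grid = scale * np.array([1e-5, 1e-4, 1e-3, 1e-2, 1e-1])
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = rng.permutation(design.n_stimuli)
    folds = np.array_split(order, min(n_folds, design.n_stimuli))
    counts_all = design.repeat_counts(spikes)
    c = design.summed_counts(spikes)
    L = design.window

    # per-stimulus S^T y
    sty_stim = np.zeros((design.n_stimuli, 2 * L))
    for s in range(design.n_stimuli):
        o, n = design.offsets[s], design.stim_lens[s]
        cs = c[o : o + n].copy()
        cs[:L] = 0.0
        idx = np.nonzero(cs)[0] + o
        if idx.size == 0:
            continue
        w = c[idx]
        for j in range(L):
            sty_stim[s, j] = design._g_ra[idx - 1 - j] @ w
            sty_stim[s, L + j] = design._g_pc[idx - 1 - j] @ w

    scores = np.zeros(len(grid))
    for fi, fold in enumerate(folds):
        train_mask = np.ones(design.n_stimuli, dtype=bool)
        train_mask[fold] = False
        A_tr = np.zeros((2 * L, 2 * L))
        sty_tr = np.zeros(2 * L)
        for s in range(design.n_stimuli):
            if train_mask[s]:
                A_tr += counts_all[s] * design._sts_blocks[s]
                sty_tr += sty_stim[s]
        y_te, rows_te = [], []
        for s in fold:
            o, n = design.offsets[s], design.stim_lens[s]
            cs = c[o : o + n]
            y_te.append(cs[L:])
            rows_te.append(design._rows32[o + L : o + n])
        y_te = np.concatenate(y_te)
        rows_te = np.concatenate(rows_te).astype(np.float64)
        if np.ptp(y_te) == 0:
            continue
        for gi, a in enumerate(grid):
            A = A_tr.copy()
            A[np.diag_indices_from(A)] += a
            k = scipy.linalg.solve(A, sty_tr, assume_a="pos")
            pred = rows_te @ k
            if np.ptp(pred) == 0:
                continue
            scores[gi] += np.corrcoef(pred, y_te)[0, 1]
    return float(grid[int(np.argmax(scores))])
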