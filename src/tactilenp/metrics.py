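"""Filter-shape metrics, resolution-dependent explained variance,
predictable variance, and vector strength.

Filter metrics follow the conventions used throughout the pipeline:

* magnitude — sum of the absolute filter values over time;
* width — total time (ms) the absolute filter exceeds a noise threshold
  set to three times the SD of the filter over the 80-100 ms tail;
* excitation index — (positive mass - negative mass) / magnitude, so +1
  is purely excitatory, 0 balanced, -1 purely suppressive.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .cortex_lnp import CorticalSpikeData

RESOLUTIONS_MS = (3, 5, 13, 66)


def filter_magnitude(k: np.ndarray) -> float:
    """Sum of absolute filter values."""
    return float(np.abs(np.asarray(k, dtype=np.float64)).sum())


def filter_width(k: np.ndarray, bin_ms: float = 1.0, tail_ms: tuple[int, int] = (80, 100)) -> float:
    """Total time (ms) the filter's absolute value exceeds the noise
    threshold (3 x SD of the 80-100 ms tail).

    The count is of all bins above threshold, not a contiguous span.
    Uses a strict inequality: an exactly-zero tail gives threshold 0, so
    the width of a noise-free filter is the size of its support.
    """
    k = np.asarray(k, dtype=np.float64)
    i0 = int(tail_ms[0] / bin_ms)
    i1 = int(tail_ms[1] / bin_ms)
    threshold = 3.0 * np.std(k[i0:i1])
    return float(np.sum(np.abs(k) > threshold) * bin_ms)


def excitation_index(k: np.ndarray) -> float:
    """(sum of positive parts - sum of negative parts) / magnitude."""
    k = np.asarray(k, dtype=np.float64)
    mag = np.abs(k).sum()
    if mag == 0:
        raise ValueError("excitation index undefined for the zero filter")
    return float((k[k > 0].sum() + k[k < 0].sum()) / mag)


def _resolution_filter(x: np.ndarray, resolution_ms: float, fs_hz: float = 1000.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth lowpass at the resolution's
    Nyquist frequency, 1000/(2*resolution_ms) Hz."""
    cutoff = 1000.0 / (2.0 * resolution_ms)
    sos = scipy.signal.butter(4, cutoff, btype="low", fs=fs_hz, output="sos")
    return scipy.signal.sosfiltfilt(sos, x)


def explained_variance_at_resolution(
    predicted: np.ndarray,
    observed: np.ndarray,
    resolution_ms: float,
    fs_hz: float = 1000.0,
) -> float:
    """Squared Pearson correlation between predicted and observed rates
    after filtering both to a temporal resolution band.

    ``resolution_ms`` is canonically one of 3, 5, 13 or 66 ms; the band
    is implemented as a zero-phase lowpass with cutoff 1000/(2*res) Hz.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape:
        raise ValueError("sequences must be aligned")
    pf = _resolution_filter(predicted, resolution_ms, fs_hz)
    of = _resolution_filter(observed, resolution_ms, fs_hz)
    if np.ptp(pf) == 0 or np.ptp(of) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = np.corrcoef(pf, of)[0, 1]
    return float(r**2)


def r2_fraction(reduced_r2: float, full_r2: float) -> float:
    """Ratio of a reduced model's R^2 to the full model's, clipped to
    [0, 1] for reporting."""
    if full_r2 <= 0:
        raise ValueError("full-model R^2 must be positive")
    return float(np.clip(reduced_r2 / full_r2, 0.0, 1.0))


def predictable_variance(trials: CorticalSpikeData | list[np.ndarray], bin_ms: float = 1.0) -> float:
    """Fraction of response variance that is repeatable across trials.

    Uses the signal-power decomposition over n repeats of the same
    stimulus: signal variance is estimated as
    ``(n * Var_t(mean) - mean_t(var across repeats)) / (n - 1)`` and
    divided by total variance (signal + trial noise).  Identical repeats
    give 1; independent repeats of a constant rate give ~0 at fine bins.
    """
    if isinstance(trials, CorticalSpikeData):
        arrs = trials.trials
    else:
        arrs = [np.asarray(t) for t in trials]
    n = len(arrs)
    if n < 2:
        raise ValueError("need at least two repeats")
    length = arrs[0].size
    if any(a.size != length for a in arrs):
        raise ValueError("repeats must have equal length")
    nb = int(length // bin_ms)
    binned = np.stack(
        [a[: int(nb * bin_ms)].reshape(nb, -1).sum(axis=1).astype(np.float64) for a in arrs]
    )
    mean_over_reps = binned.mean(axis=0)
    var_of_mean = np.var(mean_over_reps)
    noise = np.mean(np.var(binned, axis=0, ddof=1))
    signal = (n * var_of_mean - noise) / (n - 1)
    total = signal + noise
    if total <= 0:
        return 0.0
    return float(signal / total)


def vector_strength(spike_times: np.ndarray, frequency: float) -> float:
    """Resultant length of spike phases relative to a sinusoid:
    |sum exp(i*2*pi*f*t_k)| / n.  1 = perfect phase locking."""
    t = np.asarray(spike_times, dtype=np.float64)
    if t.size == 0:
        raise ValueError("vector strength undefined without spikes")
    phases = 2.0 * np.pi * frequency * t
    return float(np.abs(np.exp(1j * phases).mean()))
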