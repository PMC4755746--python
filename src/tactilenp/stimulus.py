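"""Vibrotactile stimulus generation and transformation.

All stimuli are uniformly sampled skin-displacement time series in
micrometres.  The classes of stimuli used throughout the pipeline are

* sinusoids (and, by superposition, diharmonics),
* band-limited "frozen" noise (50-800 Hz is the canonical band),
* texture-analog traces with power-law amplitude spectra, emulating the
  high-frequency skin oscillations elicited when a fingertip scans a
  textured surface, and
* "distorted" traces: the second time-derivative of a texture trace,
  renormalized to the original RMS, which keeps the frequency support
  but reweights it by f².

Band-limited noise is synthesized in the frequency domain (random phases
on the in-band bins) so the band limits are exact and the trace is
reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import dataclasses
import numpy as np

DEFAULT_SAMPLE_RATE = 20_000.0
"""Default sampling rate (Hz).  Far above twice the 800 Hz stimulus
ceiling, leaving headroom for numerically differentiated features."""


@dataclasses.dataclass(frozen=True)
class StimulusTrace:
    """A uniformly sampled skin-displacement trace.

    Parameters
    ----------
    samples
        Displacement in micrometres.
    sample_rate
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    # -- plain-text round trip ------------------------------------------------

    def save(self, path) -> None:
        """Write as single-column text with a ``sample_rate_hz=`` header."""
        header = f"sample_rate_hz={self.sample_rate!r}"
        np.savetxt(path, self.samples, header=header, comments="# ")

    @classmethod
    def load(cls, path) -> "StimulusTrace":
        with open(path) as fh:
            first = fh.readline().strip()
        sample_rate = DEFAULT_SAMPLE_RATE
        if first.startswith("#") and "sample_rate_hz=" in first:
            sample_rate = float(first.split("sample_rate_hz=")[1])
        samples = np.loadtxt(path)
        return cls(samples=np.atleast_1d(samples), sample_rate=sample_rate)


def _check_nyquist(frequency: float, sample_rate: float) -> None:
    nyquist = sample_rate / 2.0
    if not 0 < frequency < nyquist:
        raise ValueError(
            f"frequency {frequency} Hz must lie in (0, {nyquist}) Hz "
            f"(Nyquist limit for sample_rate={sample_rate} Hz)"
        )


def make_sinusoid(
    frequency: float,
    amplitude: float,
    duration: float = 1.0,
    phase: float = 0.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> StimulusTrace:
    """Pure sinusoidal skin vibration.

    ``samples[i] = amplitude * sin(2*pi*frequency*i/sample_rate + phase)``.
    """
    _check_nyquist(frequency, sample_rate)
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    return StimulusTrace(amplitude * np.sin(2 * np.pi * frequency * t + phase), sample_rate)


def make_diharmonic(
    f1: float,
    a1: float,
    f2: float,
    a2: float,
    duration: float = 1.0,
    phase2: float = 0.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> StimulusTrace:
    """Two-component harmonic stimulus (superposition of two sinusoids)."""
    s1 = make_sinusoid(f1, a1, duration, 0.0, sample_rate)
    s2 = make_sinusoid(f2, a2, duration, phase2, sample_rate)
    return StimulusTrace(s1.samples + s2.samples, sample_rate)


def _band_synthesis(
    n: int,
    sample_rate: float,
    low: float,
    high: float,
    spectral_exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Frequency-domain synthesis of band-limited noise with amplitude
    spectrum proportional to f**(-spectral_exponent) inside [low, high]."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    band = (freqs >= low) & (freqs <= high)
    if not np.any(band):
        raise ValueError("band contains no frequency bins at this duration")
    spectrum = np.zeros(freqs.size, dtype=np.complex128)
    mag = np.where(band, np.power(np.maximum(freqs, 1e-12), -spectral_exponent), 0.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spectrum[band] = mag[band] * np.exp(1j * phases[band])
    x = np.fft.irfft(spectrum, n=n)
    return x


def make_bandpass_noise(
    low: float,
    high: float,
    rms_amplitude: float,
    duration: float = 1.0,
    seed: int | np.random.Generator = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> StimulusTrace:
    """Frozen band-limited noise.

    Power outside [low, high] is exactly zero (frequency-domain
    synthesis); the RMS equals ``rms_amplitude`` exactly; the trace is a
    deterministic function of ``seed``.
    """
    nyquist = sample_rate / 2.0
    if not (0 < low < high < nyquist):
        raise ValueError(
            f"invalid band [{low}, {high}] Hz: need 0 < low < high < "
            f"Nyquist ({nyquist} Hz)"
        )
    if rms_amplitude < 0:
        raise ValueError("rms_amplitude must be non-negative")
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = _band_synthesis(n, sample_rate, low, high, 0.0, rng)
    r = np.sqrt(np.mean(x**2))
    x = x * (rms_amplitude / r) if r > 0 else x
    return StimulusTrace(x, sample_rate)


def make_texture_traces(
    n_traces: int,
    duration: float = 0.5,
    spectral_exponent: float = 1.5,
    rms_range: tuple[float, float] = (2.0, 60.0),
    seed: int | np.random.Generator = 0,
    band: tuple[float, float] = (50.0, 800.0),
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> list[StimulusTrace]:
    """Texture-analog vibration traces.

    Scanning a finger over a texture elicits skin oscillations whose
    amplitude falls off with frequency roughly as a power law; each
    generated trace has amplitude spectrum proportional to
    f**(-spectral_exponent) within ``band`` (random phases) and an RMS
    drawn log-uniformly from ``rms_range`` (micrometres).
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    if not 0.0 <= spectral_exponent <= 3.0:
        raise ValueError("spectral_exponent must lie in [0, 3]")
    lo, hi = rms_range
    if not (0 < lo <= hi):
        raise ValueError("rms_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * sample_rate))
    traces = []
    for _ in range(n_traces):
        rms = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        x = _band_synthesis(n, sample_rate, band[0], band[1], spectral_exponent, rng)
        x *= rms / np.sqrt(np.mean(x**2))
        traces.append(StimulusTrace(x, sample_rate))
    return traces


def distort_trace(trace: StimulusTrace) -> StimulusTrace:
    """Second time-derivative (acceleration) of a trace, renormalized to
    the original RMS.

    Uses second-order central differences in the interior and one-sided
    second-order differences at the two endpoints, so the length is
    preserved.  The output contains the same frequencies as the input
    but with spectral power reweighted by f².
    """
    x = trace.samples
    if x.size < 4:
        raise ValueError("trace too short to differentiate (need >= 4 samples)")
    d2 = np.empty_like(x)
    d2[1:-1] = x[2:] - 2.0 * x[1:-1] + x[:-2]
    d2[0] = 2.0 * x[0] - 5.0 * x[1] + 4.0 * x[2] - x[3]
    d2[-1] = 2.0 * x[-1] - 5.0 * x[-2] + 4.0 * x[-3] - x[-4]
    # units: per-sample second difference; the renormalization below makes
    # the absolute scale irrelevant
    in_rms = np.sqrt(np.mean(x**2))
    out_rms = np.sqrt(np.mean(d2**2))
    if out_rms > 0 and in_rms > 0:
        d2 *= in_rms / out_rms
    return StimulusTrace(d2, trace.sample_rate)


def spectral_slope(trace: StimulusTrace, band: tuple[float, float] = (50.0, 800.0)) -> float:
    """Fitted log-log slope of the amplitude spectrum within ``band``.

    A power-law trace with exponent ``e`` returns approximately ``-e``.
    """
    spec = np.abs(np.fft.rfft(trace.samples))
    freqs = np.fft.rfftfreq(trace.n_samples, d=1.0 / trace.sample_rate)
    sel = (freqs >= band[0]) & (freqs <= band[1]) & (spec > 0)
    logf = np.log(freqs[sel])
    logs = np.log(spec[sel])
    slope = np.polyfit(logf, logs, 1)[0]
    return float(slope)
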