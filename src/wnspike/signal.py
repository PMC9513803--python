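"""Filtered Gaussian white-noise stimulus generation.

The optogenetic stimulus waveform is uncorrelated zero-mean Gaussian noise
convolved with an alpha function ``t * exp(-t / tau)`` and scaled to [0, 1].
The same fixed waveform is reused across all trials of an experiment; the
actual light-power command is an affine map ``P(t) = mu + x(t) * sigma`` of
the scaled trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import resample_poly

from ._core import derive_rng

__all__ = [
    "StimulusTrace",
    "PowerTrace",
    "generate_wn_signal",
    "standardize",
    "scale_power",
    "alpha_kernel",
]


class DegenerateSignalError(ValueError):
    """Raised when an operation requires a non-constant signal."""


class InvalidPowerError(ValueError):
    """Raised when a power scaling would produce non-positive light power."""


@dataclass(frozen=True)
class StimulusTrace:
    """A sampled stimulus waveform.

    Attributes
    ----------
    samples : np.ndarray
        The waveform.  ``standardized=False`` means min-max scaled to [0, 1];
        ``standardized=True`` means zero mean, unit variance (z(t)).
    fs : float
        Sampling rate in Hz.
    tau : float
        Alpha-function time constant in ms used to generate the trace.
    seed : int
        Seed of the Gaussian draw.
    """

    samples: np.ndarray
    fs: float
    tau: float
    seed: int
    standardized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        self.samples.setflags(write=False)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self.samples) / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs * 1000.0

    def resample(self, fs_new: float) -> "StimulusTrace":
        """Polyphase resampling to a new rate (e.g. 6 kHz stimulus grid to the
        2.5 kHz analysis grid)."""
        from fractions import Fraction

        frac = Fraction(int(round(fs_new)), int(round(self.fs)))
        y = resample_poly(self.samples, frac.numerator, frac.denominator)
        return replace(self, samples=y, fs=float(fs_new))


@dataclass(frozen=True)
class PowerTrace:
    """Light-power command ``mu + x(t) * sigma_power`` in microwatts."""

    samples: np.ndarray
    mu: float
    sigma_power: float
    source_trace: StimulusTrace = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        self.samples.setflags(write=False)


def alpha_kernel(tau_ms: float, fs: float) -> np.ndarray:
    """Alpha function ``t * exp(-t/tau)`` sampled at ``fs`` over [0, 10*tau].

    The support captures >99.95% of the kernel mass.  Normalized to unit sum
    (the normalization is irrelevant after min-max scaling of the convolved
    signal, but makes the kernel a proper averaging filter on its own).
    Degenerates to a one-sample identity kernel when 10*tau is below the
    sample spacing.
    """
    n = int(round(10.0 * tau_ms * 1e-3 * fs))
    if n < 2:
        return np.array([1.0])
    t = np.arange(n) / fs  # seconds
    k = t * np.exp(-t / (tau_ms * 1e-3))
    s = k.sum()
    if s == 0.0:
        return np.array([1.0])
    return k / s


def generate_wn_signal(duration: float, fs: float, tau: float, seed: int) -> StimulusTrace:
    """Generate the alpha-filtered Gaussian white-noise stimulus.

    Parameters
    ----------
    duration : float
        Signal length in seconds (typically 1 s).
    fs : float
        Sampling rate in Hz (typically 6000).
    tau : float
        Alpha-function time constant in ms (typically 3).
    seed : int
        PRNG seed; identical arguments give bit-identical output.

    Returns
    -------
    StimulusTrace
        Min-max scaled to [0, 1] exactly.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    n = int(round(duration * fs))
    rng = derive_rng(seed, 0)
    x = rng.standard_normal(n)
    k = alpha_kernel(tau, fs)
    # zero-padded "same" convolution, then rescale to [0, 1]
    y = np.convolve(x, k, mode="full")
    off = (len(k) - 1) // 2
    y = y[off : off + n]
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise DegenerateSignalError("generated signal is constant")
    y = (y - lo) / (hi - lo)
    return StimulusTrace(samples=y, fs=float(fs), tau=float(tau), seed=int(seed))


def standardize(trace: StimulusTrace) -> StimulusTrace:
    """Affinely map a trace to zero mean and unit variance (z(t))."""
    x = trace.samples
    sd = x.std()
    if sd == 0.0:
        raise DegenerateSignalError("cannot standardize a constant signal")
    z = (x - x.mean()) / sd
    return replace(trace, samples=z, standardized=True)


def scale_power(trace: StimulusTrace, mu: float, sigma_power: float) -> PowerTrace:
    """Map a stimulus trace to light power ``P(t) = mu + x(t) * sigma_power``.

    Raises
    ------
    InvalidPowerError
        If any resulting sample is non-positive (the offset must be chosen so
        that non-positive powers are excluded).
    """
    p = mu + trace.samples * sigma_power
    if np.any(p <= 0):
        raise InvalidPowerError(
            f"power trace reaches {p.min():.4g} uW; mu must exclude non-positive values"
        )
    return PowerTrace(samples=p, mu=float(mu), sigma_power=float(sigma_power), source_trace=trace)
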