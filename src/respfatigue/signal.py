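"""Sampled-signal container and elementary filtering/resampling operations.

All physiological signals in this package are carried as :class:`SampledSignal`:
a uniformly sampled real-valued series in microvolts with an attached sampling
rate.  Time is in seconds, sample indices are 0-based and intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class SampledSignal:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Sample values in microvolts (μV).
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample time stamps in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def copy(self) -> "SampledSignal":
        return SampledSignal(self.samples.copy(), self.fs, self.t0)


def rms(x: SampledSignal | np.ndarray) -> float:
    """Root-mean-square value of a signal or plain array."""
    a = x.samples if isinstance(x, SampledSignal) else np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(a**2)))


def highpass(
    x: SampledSignal, fc: float, order: int = 3, zero_phase: bool = False
) -> SampledSignal:
    """Butterworth high-pass filter.

    Causal by default (the processing chain is causal); ``zero_phase=True``
    applies the filter forward and backward for offline analysis.

    Raises
    ------
    ValueError
        If ``fc`` is at or above the Nyquist frequency.
    """
    if fc >= x.fs / 2:
        raise ValueError(f"corner frequency {fc} Hz >= Nyquist {x.fs / 2} Hz")
    sos = sps.butter(order, fc, btype="highpass", fs=x.fs, output="sos")
    if zero_phase:
        y = sps.sosfiltfilt(sos, x.samples)
    else:
        y = sps.sosfilt(sos, x.samples)
    return SampledSignal(y, x.fs, x.t0)


def baseline_highpass(x: SampledSignal, fc: float = 1.0, order: int = 3) -> SampledSignal:
    """Remove baseline offset/drift (third-order Butterworth, 1 Hz corner)."""
    return highpass(x, fc, order=order)


def upsample_linear(x: SampledSignal, fs_new: float) -> SampledSignal:
    """Resample to a higher rate by linear interpolation.

    Sample values at time points shared by both grids are preserved exactly.
    """
    if fs_new < x.fs:
        raise ValueError("upsample_linear requires fs_new >= fs")
    n_new = int(round(x.samples.size * fs_new / x.fs))
    t_new = np.arange(n_new) / fs_new
    t_old = np.arange(x.samples.size) / x.fs
    y = np.interp(t_new, t_old, x.samples)
    return SampledSignal(y, fs_new, x.t0)


def downsample_by2(x: SampledSignal) -> SampledSignal:
    """Halve the sampling rate with an anti-alias FIR (polyphase) stage."""
    y = sps.resample_poly(x.samples, 1, 2)
    return SampledSignal(y, x.fs / 2, x.t0)
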