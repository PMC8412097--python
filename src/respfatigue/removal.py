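"""Cardiogenic-artifact removal: high-pass, template subtraction, wavelet damping.

Method family:

``HP15``/``HP35``
    Third-order Butterworth high-pass only (15 or 35 Hz corner).
``TS15``/``TS35``
    Template subtraction: past heart-cycle segments aligned at the QRS are
    averaged into a template which is subtracted at each beat; post high-pass.
``TSW15``/``TSW35``
    As TS but the template is additionally wavelet-denoised (6-level
    stationary wavelet transform, Daubechies-5).
``TSWD15``/``TSWD35``
    TSW followed by a heart-phase-synchronous multiplicative damping step in
    an 8-level stationary wavelet transform.
``DSO``
    The damping step applied directly to the input (no template subtraction).

Template work is performed at 2048 Hz (signals upsampled by linear
interpolation) for sub-sample placement precision, then brought back to the
native 1024 Hz rate.  A gate mask covering [−0.05, +0.1) s around each beat
is always produced; downstream analysis consumes it only under gating
strategy ``GO``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .qrs import QrsAnnotation
from .signal import SampledSignal, downsample_by2, highpass, upsample_linear

GATE_PRE = 0.05  # s gated before each beat
GATE_POST = 0.10  # s gated after each beat
TEMPLATE_PRE = 0.3  # s template starts before the QRS time
TAPER_RISE = 0.1  # s trapezoid rising flank
TAPER_FALL = 0.2  # s trapezoid falling flank
WAVELET = "db5"
WORK_FS = 2048.0

METHODS = (
    "NONE",
    "HP15",
    "HP35",
    "TS15",
    "TS35",
    "TSW15",
    "TSW35",
    "TSWD15",
    "TSWD35",
    "DSO",
)


@dataclass
class HeartTemplate:
    """Average heart-cycle waveform used for subtraction.

    ``samples`` run from ``pre_time`` s before the QRS time over one mean
    heart cycle, at ``fs``; tapered by a trapezoid window.
    """

    samples: np.ndarray
    fs: float
    pre_time: float = TEMPLATE_PRE
    taper_rise: float = TAPER_RISE
    taper_fall: float = TAPER_FALL

    @property
    def length(self) -> float:
        return self.samples.size / self.fs


@dataclass
class DampingTemplate:
    """Per-level damping factors over relative heart-cycle time τc.

    ``values`` has shape (n_levels, grid length), each entry in (0, 1];
    ``m_tau`` and ``theta`` are the per-level median and threshold.
    Level 1 holds the highest-frequency coefficients.
    """

    values: np.ndarray
    m_tau: np.ndarray
    theta: np.ndarray


@dataclass
class GateMask:
    """Boolean mask aligned to a signal, true inside QRS gate windows."""

    values: np.ndarray
    fs: float

    @property
    def gated_seconds(self) -> float:
        return float(np.sum(self.values)) / self.fs


def make_gate_mask(n: int, fs: float, qrs: QrsAnnotation) -> GateMask:
    """Gate windows [beat − 0.05 s, beat + 0.1 s) for every beat."""
    mask = np.zeros(n, dtype=bool)
    for t in qrs.beat_times:
        lo = int(round((t - GATE_PRE) * fs))
        hi = int(round((t + GATE_POST) * fs))
        mask[max(lo, 0) : min(hi, n)] = True
    return GateMask(mask, fs)


def remove_highpass(x: SampledSignal, fc: float) -> SampledSignal:
    """Third-order Butterworth high-pass (methods HP15 / HP35)."""
    if fc not in (15, 35, 15.0, 35.0):
        raise ValueError("corner frequency must be 15 or 35 Hz")
    return highpass(x, fc, order=3)


# ---------------------------------------------------------------------------
# stationary wavelet transform helpers
# ---------------------------------------------------------------------------

def swt_decompose(samples: np.ndarray, levels: int) -> tuple[list[np.ndarray], int]:
    """Undecimated (stationary) wavelet transform, Daubechies-5.

    The input is zero-padded at the end to a multiple of ``2**levels``.
    Returns ``(coeffs, n)`` where ``coeffs = [cA_L, cD_L, ..., cD_1]`` and
    ``n`` is the original length (for cropping after reconstruction).
    """
    n = samples.size
    block = 2**levels
    pad = (-n) % block
    data = np.concatenate([samples, np.zeros(pad)]) if pad else samples.copy()
    coeffs = pywt.swt(data, WAVELET, level=levels, trim_approx=True, norm=False)
    return [np.asarray(c) for c in coeffs], n


def swt_reconstruct(coeffs: list[np.ndarray], n: int, levels: int) -> np.ndarray:
    """Inverse of :func:`swt_decompose` (crops the padding)."""
    rec = pywt.iswt(coeffs, WAVELET, norm=False)
    return np.asarray(rec)[:n]


def _detail(coeffs: list[np.ndarray], level: int) -> np.ndarray:
    """Detail coefficients for level ``level`` (1 = highest frequency)."""
    return coeffs[len(coeffs) - level]


# ---------------------------------------------------------------------------
# template construction and subtraction
# ---------------------------------------------------------------------------

def _sliding_rms(a: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    power = np.convolve(a**2, kernel, mode="same")
    return np.sqrt(np.maximum(power, 0))


def wavelet_denoise_template(
    samples: np.ndarray, fs: float, rms_window: int = 25
) -> np.ndarray:
    """Denoise a raw template with a 6-level stationary wavelet transform.

    The three highest-frequency levels are zeroed outright.  In levels 4–6
    coefficients are zeroed where the local RMS is below the level's median
    RMS, linearly shrunk where it lies between the median and twice the
    median, and kept otherwise; a range zeroed at a coarse level is also
    zeroed at all finer levels.  This keeps high frequencies inside the QRS
    (where the artifact genuinely has them) and voids them elsewhere.
    """
    coeffs, n = swt_decompose(np.asarray(samples, dtype=float), 6)
    length = coeffs[0].size
    for lvl in (1, 2, 3):
        _detail(coeffs, lvl)[:] = 0.0
    zero_masks = {}
    for lvl in (4, 5, 6):
        d = _detail(coeffs, lvl)
        local = _sliding_rms(d, rms_window)
        med = float(np.median(local))
        if med == 0:
            zero_masks[lvl] = np.zeros(length, dtype=bool)
            continue
        gain = np.clip((local - med) / med, 0.0, 1.0)  # 0 below med, 1 above 2·med
        d *= gain
        zero_masks[lvl] = local < med
    # a zeroed range at a coarse level is zeroed at all earlier (finer) levels
    for coarse in (6, 5):
        for finer in range(4, coarse):
            d = _detail(coeffs, finer)
            d[zero_masks[coarse]] = 0.0
    return swt_reconstruct(coeffs, n, 6)


def _taper(length: int, fs: float) -> np.ndarray:
    """Trapezoid window: 0.1 s linear rise, 0.2 s linear fall."""
    w = np.ones(length)
    nr = min(int(round(TAPER_RISE * fs)), length)
    nf = min(int(round(TAPER_FALL * fs)), length)
    if nr > 1:
        w[:nr] = np.linspace(0, 1, nr, endpoint=False)
    if nf > 1:
        w[-nf:] = np.linspace(1, 0, nf + 1)[1:]
    return w


def _beat_segments(
    samples: np.ndarray, fs: float, qrs: QrsAnnotation
) -> tuple[np.ndarray, list[int], int]:
    """Heart-cycle segments aligned at the beats.

    Each segment starts ``TEMPLATE_PRE`` s before a beat and spans one mean
    heart cycle.  Beats whose segment would cross the record edge are skipped.
    Returns (segments array, start indices, segment length).
    """
    if len(qrs) < 2:
        raise ValueError("template construction requires at least 2 beats")
    seg_len = int(round(qrs.mean_rr * fs))
    starts, segs = [], []
    for t in qrs.beat_times:
        s = int(round((t - TEMPLATE_PRE) * fs))
        if s < 0 or s + seg_len > samples.size:
            continue
        starts.append(s)
        segs.append(samples[s : s + seg_len])
    if len(segs) < 2:
        raise ValueError("fewer than 2 complete heart cycles in the record")
    return np.array(segs), starts, seg_len


def _finalize_template(raw: np.ndarray, fs: float, denoise: bool) -> np.ndarray:
    """Smooth (SG order 6, length 25), optionally wavelet-denoise, taper."""
    if raw.size >= 25:
        smoothed = sps.savgol_filter(raw, 25, 6)
    else:
        smoothed = raw.copy()
    if denoise:
        smoothed = wavelet_denoise_template(smoothed, fs)
    return smoothed * _taper(smoothed.size, fs)


def build_template(
    x: SampledSignal, qrs: QrsAnnotation, denoise: bool = False
) -> HeartTemplate:
    """Template from the mean of all complete beat-aligned heart cycles."""
    segs, _, _ = _beat_segments(x.samples, x.fs, qrs)
    return HeartTemplate(_finalize_template(segs.mean(axis=0), x.fs, denoise), x.fs)


def subtract_template(
    x: SampledSignal,
    template: HeartTemplate,
    qrs: QrsAnnotation,
    post_fc: float | None = None,
) -> SampledSignal:
    """Subtract a fixed template at every beat, then optional post high-pass.

    Overlapping placements sum; beats whose placement would cross the record
    edge are skipped.  ``x`` and the template must share the sampling rate.
    """
    if template.fs != x.fs:
        raise ValueError("template and signal rates differ")
    out = x.samples.copy()
    L = template.samples.size
    for t in qrs.beat_times:
        s = int(round((t - template.pre_time) * x.fs))
        if s < 0 or s + L > out.size:
            continue
        out[s : s + L] -= template.samples
    y = SampledSignal(out, x.fs, x.t0)
    if post_fc is not None:
        y = highpass(y, post_fc, order=3)
    return y


def template_subtract(
    x: SampledSignal,
    qrs: QrsAnnotation,
    denoise: bool = False,
    post_fc: float | None = 15.0,
    causal: bool = True,
) -> SampledSignal:
    """Full template-subtraction stage (methods TS / TSW).

    The input is upsampled to 2048 Hz, a template is subtracted at each beat
    (running causal mean over all past heart cycles by default; the first
    beat uses its own segment), the result is downsampled back and post
    high-pass filtered.  ``causal=False`` uses the global all-beat mean.
    """
    up = upsample_linear(x, WORK_FS)
    fs = up.fs
    segs, starts, seg_len = _beat_segments(up.samples, fs, qrs)
    out = up.samples.copy()
    csum = np.cumsum(segs, axis=0)
    global_mean = segs.mean(axis=0)
    for k, s in enumerate(starts):
        if causal:
            raw = segs[0] if k == 0 else csum[k - 1] / k
        else:
            raw = global_mean
        out[s : s + seg_len] -= _finalize_template(raw, fs, denoise)
    y = downsample_by2(SampledSignal(out, fs, x.t0))
    # polyphase stage can change the length by one sample; match the input
    if len(y) != len(x):
        pad = len(x) - len(y)
        y = SampledSignal(
            np.pad(y.samples, (0, max(pad, 0)))[: len(x)], y.fs, y.t0
        )
    if post_fc is not None:
        y = highpass(y, post_fc, order=3)
    return y


# ---------------------------------------------------------------------------
# wavelet damping stage
# ---------------------------------------------------------------------------

def _cycles(
    n: int, fs: float, qrs: QrsAnnotation
) -> tuple[list[tuple[int, int]], int]:
    """Complete heart cycles [beat−0.3 s, next beat−0.3 s) inside the record
    plus the common τc grid length (round(mean_rr · fs))."""
    if len(qrs) < 2:
        raise ValueError("damping requires at least 2 beats")
    grid = int(round(qrs.mean_rr * fs))
    bounds = []
    times = qrs.beat_times
    for k in range(len(times) - 1):
        a = int(round((times[k] - TEMPLATE_PRE) * fs))
        b = int(round((times[k + 1] - TEMPLATE_PRE) * fs))
        if a >= 0 and b <= n and b - a >= 2:
            bounds.append((a, b))
    if len(bounds) < 2:
        raise ValueError("fewer than 2 complete heart cycles")
    return bounds, grid


def compute_warca(
    coeffs: list[np.ndarray], fs: float, qrs: QrsAnnotation, n_levels: int = 8
) -> np.ndarray:
    """Average remaining cardiogenic artifact profile wARCA per level.

    For each wavelet level the rectified coefficients of every complete heart
    cycle are linearly resampled to a common relative-cycle-time grid and
    averaged across beats.  Shape: (n_levels, grid).
    """
    n = coeffs[0].size
    bounds, grid = _cycles(n, fs, qrs)
    tau = np.linspace(0.0, 1.0, grid)
    warca = np.zeros((n_levels, grid))
    for lvl in range(1, n_levels + 1):
        d = np.abs(_detail(coeffs, lvl))
        acc = np.zeros(grid)
        for a, b in bounds:
            src = np.linspace(0.0, 1.0, b - a)
            acc += np.interp(tau, src, d[a:b])
        warca[lvl - 1] = acc / len(bounds)
    return warca


def build_damping_template(warca: np.ndarray) -> DampingTemplate:
    """Damping factors from the per-level artifact profiles.

    Per level i (1 = finest): mτ = median over τc of wARCA_i, threshold
    θ_i = (1 + (8 − i)/16) · mτ.  Where the profile stays below θ_i nothing
    is damped (factor 1); above it the coefficient is attenuated toward the
    baseline by mτ / wARCA, clipped to (0, 1].
    """
    n_levels, grid = warca.shape
    values = np.ones((n_levels, grid))
    m_tau = np.median(warca, axis=1)
    levels = np.arange(1, n_levels + 1)
    theta = (1 + (8 - levels) / 16) * m_tau
    for i in range(n_levels):
        if m_tau[i] <= 0:
            continue  # degenerate level left undamped
        prof = warca[i]
        above = prof >= theta[i]
        with np.errstate(divide="ignore"):
            ratio = np.where(prof > 0, m_tau[i] / np.maximum(prof, 1e-300), 1.0)
        values[i, above] = np.clip(ratio[above], 1e-12, 1.0)
    return DampingTemplate(values, m_tau, theta)


def apply_damping(
    x: SampledSignal,
    qrs: QrsAnnotation,
    n_levels: int = 8,
    damping: DampingTemplate | None = None,
) -> SampledSignal:
    """Heart-phase-synchronous multiplicative damping in the SWT domain.

    The signal is decomposed into ``n_levels`` stationary-wavelet levels;
    within each complete heart cycle every level is multiplied by the
    damping template mapped from relative cycle time back to absolute time
    (nearest grid point).  Samples outside any complete cycle, and the
    approximation level, pass through unmodified.
    """
    coeffs, n = swt_decompose(x.samples, n_levels)
    bounds, grid = _cycles(coeffs[0].size, x.fs, qrs)
    if damping is None:
        warca = compute_warca(coeffs, x.fs, qrs, n_levels)
        damping = build_damping_template(warca)
    for lvl in range(1, n_levels + 1):
        d = _detail(coeffs, lvl)
        row = damping.values[lvl - 1]
        for a, b in bounds:
            idx = np.round(np.linspace(0, grid - 1, b - a)).astype(int)
            d[a:b] *= row[idx]
    return SampledSignal(swt_reconstruct(coeffs, n, n_levels), x.fs, x.t0)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def run_removal(
    x: SampledSignal, qrs: QrsAnnotation, method: str = "TSWD15", gating: str = "GN"
) -> tuple[SampledSignal, GateMask]:
    """Run one artifact-removal variant and build the QRS gate mask.

    ``gating`` is carried as metadata: the mask is always computed and is
    consumed downstream only under strategy ``GO``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if gating not in ("GN", "GO"):
        raise ValueError("gating must be 'GN' or 'GO'")
    mask = make_gate_mask(len(x), x.fs, qrs)
    if method == "NONE":
        return x.copy(), mask
    if method in ("HP15", "HP35"):
        return remove_highpass(x, float(method[2:])), mask
    if method == "DSO":
        return apply_damping(x, qrs), mask
    fc = float(method[-2:])
    denoise = method.startswith("TSW")
    y = template_subtract(x, qrs, denoise=denoise, post_fc=fc)
    if method.startswith("TSWD"):
        y = apply_damping(y, qrs)
    return y, mask
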