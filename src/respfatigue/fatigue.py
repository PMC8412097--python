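"""Epoch-wise fatigue indexes at 8 Hz: MNF, SMR5 and fuzzy approximate entropy.

A fatigue value is computed every 0.125 s from the ``Ne`` most recent
samples (epoch sizes 128–1024 at 1024 Hz, i.e. 0.125–1 s).  Under gating
strategy ``GN`` the gate mask is ignored; under ``GO`` gated samples are
omitted and the epoch reaches further back to collect ``Ne`` ungated
samples.  Series from short epochs can be moving-average smoothed so that
every output value reflects 1 s of signal, and are normalized against the
linear trend of the uncontaminated 60%-MVC reference series so that its
fitted line runs from 0 at t = 0 s to 1 at t = 60 s.

MNF (spectral centroid) falls with fatigue; SMR5, the spectral moments
ratio M(−1)/M(5), rises as the spectrum compresses toward low frequencies;
fApEn quantifies waveform regularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.regression.linear_model import burg as _burg

from .removal import GateMask
from .signal import SampledSignal

OUTPUT_RATE = 8.0  # fatigue values per second
HOP = 0.125  # s between output ticks
EPOCH_SIZES = (128, 256, 512, 1024)
FATIGUE_ALGOS = ("MNF", "SMR5", "fApEn")


@dataclass
class EpochSpec:
    """Epoch size in samples, output hop and gating strategy."""

    ne: int = 256
    hop: float = HOP
    gating: str = "GN"

    def __post_init__(self) -> None:
        if self.ne not in EPOCH_SIZES:
            raise ValueError(f"epoch size must be one of {EPOCH_SIZES}")
        if self.gating not in ("GN", "GO"):
            raise ValueError("gating must be 'GN' or 'GO'")


@dataclass
class PsdEstimate:
    """One-sided power spectral density with its frequency grid and the
    lower integration bound ``bl`` (Hz) excluding low-frequency bins."""

    freqs: np.ndarray
    power: np.ndarray
    method: str = "welch"
    bl: float = 0.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < -1e-12):
            raise ValueError("power densities must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be ascending")


@dataclass
class FatigueSeries:
    """Fatigue-index values on the fixed 8 Hz output grid.

    ``values`` may contain NaN for ticks whose epoch was unavailable
    (lookback before the record start, or too few ungated samples under GO).
    """

    times: np.ndarray
    values: np.ndarray
    fd: str
    flavor: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must match")

    @property
    def rate(self) -> float:
        if self.times.size < 2:
            return OUTPUT_RATE
        return 1.0 / float(np.mean(np.diff(self.times)))

    def window(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Finite values with t_lo < t <= t_hi."""
        m = (self.times > t_lo) & (self.times <= t_hi) & np.isfinite(self.values)
        return self.values[m]


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def make_epochs(
    x: SampledSignal, mask: GateMask | None, spec: EpochSpec
) -> list[tuple[float, np.ndarray | None]]:
    """One epoch per 0.125 s output tick.

    GN: the ``ne`` most recent samples regardless of the mask.  GO: the
    ``ne`` most recent ungated samples, concatenated across gate gaps.
    Ticks that cannot be served yield ``None``.
    """
    fs = x.fs
    ne = spec.ne
    n = x.samples.size
    hop_n = int(round(spec.hop * fs))
    if spec.gating == "GO":
        if mask is None:
            raise ValueError("gating strategy GO requires a gate mask")
        keep = ~mask.values
    epochs: list[tuple[float, np.ndarray | None]] = []
    for end in range(hop_n, n + 1, hop_n):
        t = end / fs
        if spec.gating == "GN":
            epoch = x.samples[end - ne : end] if end >= ne else None
        else:
            sel = np.flatnonzero(keep[:end])
            epoch = x.samples[sel[-ne:]] if sel.size >= ne else None
        epochs.append((t, epoch))
    return epochs


# ---------------------------------------------------------------------------
# spectral estimation
# ---------------------------------------------------------------------------

def psd_welch(epoch: np.ndarray, fs: float, kw: int = 15, bl: float = 0.0) -> PsdEstimate:
    """Welch PSD with ``kw`` Hann-tapered half-overlapped subsegments."""
    epoch = np.asarray(epoch, dtype=float)
    nperseg = 2 * epoch.size // (kw + 1)
    if nperseg < 8:
        raise ValueError(f"kw={kw} incompatible with epoch length {epoch.size}")
    f, p = sps.welch(
        epoch,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return PsdEstimate(f, p, method=f"welch(kw={kw})", bl=bl)


def psd_burg(epoch: np.ndarray, fs: float, order: int = 10, bl: float = 0.0) -> PsdEstimate:
    """Parametric PSD from a Burg autoregressive fit.

    The epoch is linearly detrended before the fit (a residual baseline
    would dominate the low-order spectral moments).  Evaluated on the rFFT
    grid of the epoch length.
    """
    epoch = np.asarray(epoch, dtype=float)
    if order >= epoch.size:
        raise ValueError("AR order must be below the epoch length")
    epoch = sps.detrend(epoch, type="linear")
    ar, sigma2 = _burg(epoch, order=order, demean=True)
    nfft = epoch.size
    a = np.zeros(nfft)
    a[0] = 1.0
    a[1 : order + 1] = -np.asarray(ar)
    denom = np.abs(np.fft.rfft(a)) ** 2
    f = np.fft.rfftfreq(nfft, 1 / fs)
    p = sigma2 / fs / np.maximum(denom, 1e-300)
    return PsdEstimate(f, p, method=f"burg({order})", bl=bl)


def mnf(psd: PsdEstimate, bl: float | None = None) -> float:
    """Mean (centroid) frequency of the PSD above the lower bound ``bl``."""
    bl = psd.bl if bl is None else bl
    m = psd.freqs >= bl
    total = float(np.sum(psd.power[m]))
    if total <= 0:
        return float("nan")
    return float(np.sum(psd.freqs[m] * psd.power[m]) / total)


def smr5(psd: PsdEstimate, bl: float | None = None) -> float:
    """Spectral moments ratio of order five: M(−1) / M(5) over f >= bl.

    Rises as the spectrum compresses toward low frequencies; invariant to
    PSD amplitude scaling.  Bins at f = 0 are excluded (undefined f^−1).
    """
    bl = psd.bl if bl is None else bl
    m = (psd.freqs >= bl) & (psd.freqs > 0)
    p = psd.power[m]
    f = psd.freqs[m]
    m5 = float(np.sum(f**5 * p))
    if m5 <= 0:
        return float("nan")
    return float(np.sum(p / f) / m5)


def fapen(epoch: np.ndarray, m: int = 2, r_factor: float = 0.25) -> float:
    """Fuzzy approximate entropy.

    Embedding dimension ``m``, tolerance ``r = r_factor · SD(epoch)``,
    exponential membership exp(−(d/r)²) on Chebyshev distances between
    mean-removed templates; fApEn = ln φ(m) − ln φ(m+1).  A zero-variance
    epoch returns 0 by convention.
    """
    u = np.asarray(epoch, dtype=float)
    if u.size <= m + 1:
        raise ValueError("epoch too short for the embedding dimension")
    r = r_factor * float(u.std())
    if r == 0:
        return 0.0

    def phi(mm: int) -> float:
        nvec = u.size - mm + 1
        X = np.lib.stride_tricks.sliding_window_view(u, mm)[:nvec].astype(float)
        X = X - X.mean(axis=1, keepdims=True)
        d = squareform(pdist(X, metric="chebyshev"))
        sim = np.exp(-((d / r) ** 2))
        np.fill_diagonal(sim, 0.0)
        return float(sim.sum() / (nvec * (nvec - 1)))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return 0.0
    return float(np.log(p_m) - np.log(p_m1))


# ---------------------------------------------------------------------------
# series assembly, smoothing, normalization
# ---------------------------------------------------------------------------

def compute_fatigue_series(
    x: SampledSignal,
    mask: GateMask | None,
    fd: str = "SMR5",
    spec: EpochSpec | None = None,
    psd_method: str = "burg",
    psd_param: int | None = None,
    bl: float = 35.0,
    fapen_m: int = 2,
    fapen_r: float = 0.25,
) -> FatigueSeries:
    """Epoch-wise fatigue index at 8 Hz.

    ``psd_method`` is ``"burg"`` (param = AR order, default 10) or
    ``"welch"`` (param = number of subsegments kw, default 15); ignored for
    fApEn, whose low-frequency exclusion is delegated to the removal stage's
    high-pass corner.
    """
    if fd not in FATIGUE_ALGOS:
        raise ValueError(f"fd must be one of {FATIGUE_ALGOS}")
    spec = spec or EpochSpec()
    epochs = make_epochs(x, mask, spec)
    times = np.array([t for t, _ in epochs])
    values = np.full(times.size, np.nan)
    for i, (_, epoch) in enumerate(epochs):
        if epoch is None:
            continue
        if fd == "fApEn":
            values[i] = fapen(epoch, m=fapen_m, r_factor=fapen_r)
            continue
        if psd_method == "burg":
            est = psd_burg(epoch, x.fs, order=psd_param or 10, bl=bl)
        elif psd_method == "welch":
            est = psd_welch(epoch - epoch.mean(), x.fs, kw=psd_param or 15, bl=bl)
        else:
            raise ValueError("psd_method must be 'burg' or 'welch'")
        values[i] = mnf(est) if fd == "MNF" else smr5(est)
    meta = {
        "ne": spec.ne,
        "gating": spec.gating,
        "bl": bl,
        "psd": psd_method if fd != "fApEn" else None,
    }
    return FatigueSeries(times, values, fd=fd, flavor="raw", meta=meta)


def smoothing_length(ne: int, fs: float = 1024.0) -> int:
    """Moving-average length so each value covers 1 s of signal:
    k = (1 s − Le)/0.125 s + 1, i.e. 8, 7, 5, 1 for Ne = 128…1024."""
    le = ne / fs
    return int(round((1.0 - le) / HOP)) + 1


def smooth_to_1s(series: FatigueSeries, ne: int | None = None) -> FatigueSeries:
    """Causal NaN-aware moving average to 1 s information content."""
    if series.flavor != "raw":
        raise ValueError("smoothing applies to raw series")
    ne = ne or series.meta.get("ne", 256)
    k = smoothing_length(ne)
    v = series.values
    out = np.full(v.size, np.nan)
    for i in range(v.size):
        win = v[max(0, i - k + 1) : i + 1]
        win = win[np.isfinite(win)]
        if win.size:
            out[i] = win.mean()
    return FatigueSeries(series.times, out, series.fd, "smoothed", dict(series.meta))


def fit_reference_line(xi60: FatigueSeries, t_max: float = 60.0) -> tuple[float, float]:
    """Least-squares line through the reference series on 0 < t < 60 s.

    Returns (value at 0 s, value at 60 s) of the fitted line G60.
    """
    m = (xi60.times > 0) & (xi60.times < t_max) & np.isfinite(xi60.values)
    if np.sum(m) < 3:
        raise ValueError("too few reference points for the regression")
    t, v = xi60.times[m], xi60.values[m]
    slope, intercept = np.polyfit(t, v, 1)
    return float(intercept), float(intercept + slope * t_max)


def normalize(
    phi: FatigueSeries, xi60: FatigueSeries, tol: float = 1e-9
) -> FatigueSeries:
    """Normalize a fatigue series against the 60%-MVC reference trend.

    The output is ``(phi − G60(0)) / (G60(60) − G60(0))`` where G60 is the
    regression line of the raw reference series; by construction the
    normalized reference evolves (in trend) from 0 to 1 over the minute,
    regardless of the index's native range or direction.
    """
    if phi.fd != xi60.fd:
        raise ValueError("series and reference must use the same fatigue index")
    g0, g60 = fit_reference_line(xi60)
    denom = g60 - g0
    # degeneracy is judged relative to the index's native scale: indexes such
    # as SMR5 live at ~1e-12, MNF at ~1e2
    scale = max(abs(g0), abs(g60), float(np.nanstd(xi60.values)))
    if abs(denom) <= tol * max(scale, 1e-300):
        raise ValueError("degenerate normalization: reference trend is flat")
    values = (phi.values - g0) / denom
    return FatigueSeries(phi.times, values, phi.fd, "normalized", dict(phi.meta))
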