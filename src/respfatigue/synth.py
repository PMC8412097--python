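"""Construction of artificial test signals and surrogate sources.

The test bench mimics respiratory sEMG contaminated by the heart's electrical
activity.  A (real or surrogate) limb sEMG record with a known fatigue
trajectory is modulated by a breathing activity pattern and added to a
preprocessed ECG whose beat morphology varies with a simulated lung-volume
signal.  The contamination strength is parameterized by the EMG level η —
the ratio of unmodulated sEMG RMS to QRS peak-to-peak amplitude — so small η
means heavy contamination.

Surrogate source generators (band-limited stochastic sEMG with a programmed
mean-frequency decline; two-lead parametric ECG with controllable beat
irregularity) make the whole chain testable without any recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .qrs import QrsAnnotation
from .signal import SampledSignal, rms

QRS_PRE = 0.05  # s before a detected QRS considered "within the QRS segment"
QRS_POST = 0.10  # s after


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class BreathingPattern:
    """Breathing activity pattern: inspiration plateau at full activity,
    expiration plateau at ``exp_activity``, smooth transitions."""

    insp_duration: float = 1.0
    exp_duration: float = 3.0
    exp_activity: float = 0.3
    transition_duration: float = 0.1

    def __post_init__(self) -> None:
        if self.insp_duration <= 0 or self.exp_duration <= 0:
            raise ValueError("phase durations must be positive")
        if not (0 <= self.exp_activity <= 1):
            raise ValueError("exp_activity must be in [0, 1]")
        if self.transition_duration >= min(self.insp_duration, self.exp_duration):
            raise ValueError("transition must be shorter than either phase")

    @property
    def period(self) -> float:
        return self.insp_duration + self.exp_duration


@dataclass
class ContaminationSpec:
    """EMG level η, MVC load level Λ (% MVC) and ECG channel (I or A)."""

    eta: float
    mvc_level: int = 60
    channel: str = "A"

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.channel not in ("I", "A"):
            raise ValueError("channel must be 'I' or 'A'")


@dataclass
class SurrogateEmgSpec:
    """Broadband stochastic sEMG whose short-time mean frequency moves
    linearly from ``mnf_start`` to ``mnf_end`` over the record."""

    duration: float = 60.0
    fs: float = 1024.0
    mnf_start: float = 130.0
    mnf_end: float = 85.0
    band_width: float = 80.0
    seed: int = 0
    amplitude_rms: float = 50.0  # μV

    def __post_init__(self) -> None:
        if not (0 < self.mnf_end <= self.mnf_start < self.fs / 2):
            raise ValueError("require 0 < mnf_end <= mnf_start < Nyquist")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SurrogateEcgSpec:
    """Two-lead parametric ECG with RR jitter and per-beat shape variation."""

    duration: float = 60.0
    fs: float = 1024.0
    heart_rate: float = 72.0
    beat_jitter: float = 0.05
    shape_irregularity: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.beat_jitter < 0 or self.shape_irregularity < 0:
            raise ValueError("jitter and irregularity must be >= 0")


# ---------------------------------------------------------------------------
# breathing modulation and lung-volume weighting
# ---------------------------------------------------------------------------

def make_breathing_modulation(
    pattern: BreathingPattern, duration: float, fs: float
) -> SampledSignal:
    """Periodic muscular-activity pattern MSM(t).

    Plateau 1 during inspiration, ``exp_activity`` during expiration, with
    raised-cosine ramps of ``transition_duration`` at each phase change.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(int(round(duration * fs))) / fs
    tau = np.mod(t, pattern.period)
    a = pattern.exp_activity
    d = pattern.transition_duration
    ti = pattern.insp_duration
    out = np.full(t.size, a)
    # ramp up into inspiration
    m = tau < d
    out[m] = a + (1 - a) * 0.5 * (1 - np.cos(np.pi * tau[m] / d))
    # inspiration plateau
    out[(tau >= d) & (tau < ti)] = 1.0
    # ramp down into expiration
    m = (tau >= ti) & (tau < ti + d)
    out[m] = 1 + (a - 1) * 0.5 * (1 - np.cos(np.pi * (tau[m] - ti) / d))
    return SampledSignal(out, fs)


def make_volume_weighting(
    pattern: BreathingPattern,
    duration: float,
    fs: float,
    rise_time: float = 0.5,
    decay_tau: float = 1.5,
) -> SampledSignal:
    """Lung-volume-like weighting WSC(t) in [0, 1].

    Steep raised-cosine ascent over ``rise_time`` at the start of inspiration,
    plateau at 1 for the rest of the inspiration, exponential decay with time
    constant ``decay_tau`` during expiration.  Periodic and continuous.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rise_time = min(rise_time, pattern.insp_duration)
    t = np.arange(int(round(duration * fs))) / fs
    tau = np.mod(t, pattern.period)
    ti = pattern.insp_duration
    w0 = float(np.exp(-pattern.exp_duration / decay_tau))  # end-of-expiration value
    out = np.empty(t.size)
    m = tau < rise_time
    out[m] = w0 + (1 - w0) * 0.5 * (1 - np.cos(np.pi * tau[m] / rise_time))
    out[(tau >= rise_time) & (tau < ti)] = 1.0
    m = tau >= ti
    out[m] = np.exp(-(tau[m] - ti) / decay_tau)
    return SampledSignal(out, fs)


# ---------------------------------------------------------------------------
# ECG preprocessing and mixing
# ---------------------------------------------------------------------------

def _qrs_mask(n: int, fs: float, qrs: QrsAnnotation) -> np.ndarray:
    """Boolean mask, true on [beat - 0.05 s, beat + 0.1 s) for each beat."""
    mask = np.zeros(n, dtype=bool)
    for t in qrs.beat_times:
        lo = int(round((t - QRS_PRE) * fs))
        hi = int(round((t + QRS_POST) * fs))
        mask[max(lo, 0) : min(hi, n)] = True
    return mask


def savgol_ecg_denoise(ecg: SampledSignal, qrs: QrsAnnotation) -> SampledSignal:
    """Piecewise Savitzky–Golay smoothing of an ECG record.

    Inside the QRS vicinity ([−0.05, +0.1) s around each beat) an order-5,
    length-15 filter preserves the sharp complex; elsewhere an order-3,
    length-25 filter attenuates broadband (EMG-like) components.
    """
    if ecg.samples.size < 25:
        raise ValueError("record shorter than the filter length")
    smooth_wide = sps.savgol_filter(ecg.samples, 25, 3)
    smooth_qrs = sps.savgol_filter(ecg.samples, 15, 5)
    mask = _qrs_mask(ecg.samples.size, ecg.fs, qrs)
    out = np.where(mask, smooth_qrs, smooth_wide)
    return SampledSignal(out, ecg.fs, ecg.t0)


def mix_ecg_channels(
    ecg_i: SampledSignal, ecg_ii: SampledSignal, wsc: SampledSignal
) -> SampledSignal:
    """Convex per-sample mix of two ECG leads weighted by the lung-volume
    signal: ``(1 − WSC)·ECG_I + WSC·ECG_II``."""
    if not (len(ecg_i) == len(ecg_ii) == len(wsc)) or not (
        ecg_i.fs == ecg_ii.fs == wsc.fs
    ):
        raise ValueError("channel/weight length or rate mismatch")
    out = (1 - wsc.samples) * ecg_i.samples + wsc.samples * ecg_ii.samples
    return SampledSignal(out, ecg_i.fs, ecg_i.t0)


def qrs_peak_to_peak(ecg_i: SampledSignal, qrs: QrsAnnotation) -> float:
    """Representative QRS peak-to-peak amplitude of lead I.

    Median over beats of (max − min) inside the [−0.05, +0.1) s window.
    """
    if len(qrs) == 0:
        raise ValueError("at least one beat required")
    fs = ecg_i.fs
    n = ecg_i.samples.size
    pps = []
    for t in qrs.beat_times:
        lo = max(int(round((t - QRS_PRE) * fs)), 0)
        hi = min(int(round((t + QRS_POST) * fs)), n)
        if hi - lo > 1:
            pps.append(float(np.ptp(ecg_i.samples[lo:hi])))
    if not pps:
        raise ValueError("no usable beat windows")
    return float(np.median(pps))


# ---------------------------------------------------------------------------
# test-signal assembly
# ---------------------------------------------------------------------------

def contamination_gain(eta: float, qrs_pp: float, emg_rms: float) -> float:
    """EMG scaling gain g = η · QRS_pp / RMS(unmodulated EMG)."""
    if emg_rms <= 0:
        raise ValueError("EMG RMS must be positive")
    return eta * qrs_pp / emg_rms


def build_test_signal(
    emg_mod: SampledSignal,
    ecg: SampledSignal,
    spec: ContaminationSpec,
    qrs_pp: float,
    emg_rms: float,
) -> SampledSignal:
    """Artificial test signal ATS = ECG + g · (modulated EMG).

    ``emg_mod`` is the breathing-modulated sEMG; ``emg_rms`` is the RMS of
    the *unmodulated* sEMG record (the η convention references the static
    contraction's power, not the modulated one).
    """
    if len(emg_mod) != len(ecg) or emg_mod.fs != ecg.fs:
        raise ValueError("EMG and ECG must share length and rate")
    g = contamination_gain(spec.eta, qrs_pp, emg_rms)
    return SampledSignal(ecg.samples + g * emg_mod.samples, ecg.fs, ecg.t0)


def build_reference_signals(
    emg: SampledSignal, emg_mod: SampledSignal, qrs_pp: float
) -> tuple[SampledSignal, SampledSignal]:
    """Uncontaminated comparison signals (RSM, RS).

    Both are pure sEMG scaled to the power of the η = 0.2 contamination case:
    RSM is the modulated variant (the reference for normalization), RS the
    unmodulated one.
    """
    g = contamination_gain(0.2, qrs_pp, rms(emg))
    rsm = SampledSignal(g * emg_mod.samples, emg_mod.fs, emg_mod.t0)
    rs = SampledSignal(g * emg.samples, emg.fs, emg.t0)
    return rsm, rs


# ---------------------------------------------------------------------------
# surrogate sources
# ---------------------------------------------------------------------------

def generate_surrogate_emg(spec: SurrogateEmgSpec) -> SampledSignal:
    """Zero-mean stochastic sEMG with a programmed mean-frequency trajectory.

    White Gaussian noise is filtered frame-wise (Hann windows, 50% overlap,
    overlap-add) with a Gaussian band centered on the instantaneous target
    mean frequency, which moves linearly from ``mnf_start`` to ``mnf_end``.
    The Gaussian band is symmetric, so the spectral centroid tracks the
    band center.  Deterministic for a fixed seed.
    """
    fs = spec.fs
    n = int(round(spec.duration * fs))
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(n)
    win_len = int(round(0.5 * fs))
    win_len -= win_len % 2
    hop = win_len // 2
    window = sps.windows.hann(win_len, sym=False)
    freqs = np.fft.rfftfreq(win_len, 1 / fs)
    sigma = spec.band_width / 2
    out = np.zeros(n + win_len)
    padded = np.concatenate([noise, np.zeros(win_len)])
    for start in range(0, n, hop):
        t_center = (start + win_len / 2) / fs
        frac = np.clip(t_center / spec.duration, 0, 1)
        fc = spec.mnf_start + (spec.mnf_end - spec.mnf_start) * frac
        seg = padded[start : start + win_len] * window
        spec_f = np.fft.rfft(seg)
        h = np.exp(-0.5 * ((freqs - fc) / sigma) ** 2)
        out[start : start + win_len] += np.fft.irfft(spec_f * h, n=win_len)
    out = out[:n]
    out -= out.mean()
    r = rms(out)
    if r > 0:
        out *= spec.amplitude_rms / r
    return SampledSignal(out, fs)


# beat morphology: (name, center offset s, width s, amplitude) per lead,
# amplitudes in μV.  Lead II is the same heart seen with larger R/T.
_BEAT_WAVES_I = (
    ("P", -0.200, 0.025, 120.0),
    ("Q", -0.020, 0.008, -120.0),
    ("R", 0.000, 0.011, 1000.0),
    ("S", 0.022, 0.009, -250.0),
    ("T", 0.300, 0.060, 300.0),
)
_BEAT_WAVES_II = (
    ("P", -0.200, 0.025, 150.0),
    ("Q", -0.020, 0.008, -80.0),
    ("R", 0.000, 0.012, 1400.0),
    ("S", 0.022, 0.010, -350.0),
    ("T", 0.305, 0.065, 450.0),
)


def generate_surrogate_ecg(
    spec: SurrogateEcgSpec,
) -> tuple[SampledSignal, SampledSignal, QrsAnnotation]:
    """Two synchronized surrogate ECG leads plus ground-truth beat times.

    Each beat is a sum of Gaussian bumps (P, Q, R, S, T).  Per-beat amplitude
    and width multipliers scale with ``shape_irregularity`` and RR intervals
    jitter with ``beat_jitter``; perturbations are shared between leads (the
    same heart drives both).  Beat times mark the R peak.
    """
    fs = spec.fs
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)
    rr0 = 60.0 / spec.heart_rate

    ch1 = np.zeros(n)
    ch2 = np.zeros(n)
    beat_times = []
    t_beat = 0.5
    while t_beat < spec.duration - 0.0:
        beat_times.append(t_beat)
        # per-beat shared perturbations
        amp_mult = 1 + spec.shape_irregularity * rng.standard_normal(5)
        wid_mult = 1 + 0.5 * spec.shape_irregularity * rng.standard_normal(5)
        wid_mult = np.clip(wid_mult, 0.3, 3.0)
        lo = max(int((t_beat - 0.5) * fs), 0)
        hi = min(int((t_beat + 0.6) * fs), n)
        tt = t[lo:hi]
        for ch, waves in ((ch1, _BEAT_WAVES_I), (ch2, _BEAT_WAVES_II)):
            acc = np.zeros(tt.size)
            for k, (_, off, wid, amp) in enumerate(waves):
                acc += (
                    amp
                    * amp_mult[k]
                    * np.exp(-0.5 * ((tt - t_beat - off) / (wid * wid_mult[k])) ** 2)
                )
            ch[lo:hi] += acc
        rr = rr0 * (1 + spec.beat_jitter * rng.standard_normal())
        t_beat += max(rr, 0.3)
    ann = QrsAnnotation(np.array(beat_times), fs)
    return SampledSignal(ch1, fs), SampledSignal(ch2, fs), ann
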