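"""QRS detection and beat-time refinement.

The detector follows a structural-intensity scheme: evidence for a QRS
complex is accumulated from extrema of the low-pass filtered second
derivative of the signal across a set of scales (filter cut-offs).  Extrema
that persist across many scales, with large amplitude, score high; peaks of
the resulting evidence above half its maximum are taken as beats.

A subsequent refinement step fine-tunes each beat time by cross-correlating
its local segment against the running average beat, which enables precise
template placement downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal import SampledSignal


@dataclass
class QrsAnnotation:
    """Ordered heartbeat event times.

    ``beat_times`` are in seconds relative to the record start; ``fs_ref`` is
    the sampling rate the times were derived at (used when converting to
    sample indices).
    """

    beat_times: np.ndarray
    fs_ref: float

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if not (self.fs_ref > 0):
            raise ValueError("fs_ref must be positive")

    def __len__(self) -> int:
        return self.beat_times.size

    @property
    def mean_rr(self) -> float:
        """Mean RR interval in seconds (requires >= 2 beats)."""
        if self.beat_times.size < 2:
            raise ValueError("mean_rr requires at least 2 beats")
        return float(np.mean(np.diff(self.beat_times)))

    def indices(self, fs: float | None = None) -> np.ndarray:
        """Beat times as 0-based sample indices at rate ``fs`` (default fs_ref)."""
        fs = self.fs_ref if fs is None else fs
        return np.round(self.beat_times * fs).astype(int)


@dataclass
class DetectorConfig:
    """Structural-intensity detector parameters.

    ``n_scales`` low-pass cut-offs are log-spaced between ``fc_min`` and
    ``fc_max``; the detection threshold is ``threshold_fraction`` times the
    maximum of the evidence function.  ``refractory`` suppresses double
    detections closer than a physiological minimum RR.
    """

    n_scales: int = 28
    threshold_fraction: float = 0.5
    refine: bool = True
    fc_min: float = 8.0
    fc_max: float = 45.0
    refractory: float = 0.25

    def __post_init__(self) -> None:
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if not (0 < self.threshold_fraction < 1):
            raise ValueError("threshold_fraction must be in (0, 1)")


def _scale_stack(x: SampledSignal, cfg: DetectorConfig) -> tuple[np.ndarray, np.ndarray]:
    """|second derivative| of the low-pass filtered signal at each scale.

    Each row is |d²/dt²| of the signal smoothed at one scale (cut-off):
    smoothing first suppresses broadband EMG so the curvature evidence is
    dominated by the QRS complex; rectification makes detection
    polarity-invariant; zero-phase filtering keeps extrema aligned across
    scales.  Rows are ordered coarsest (lowest cut-off) first.
    """
    cutoffs = np.geomspace(cfg.fc_min, cfg.fc_max, cfg.n_scales)
    stack = np.empty((cfg.n_scales, x.samples.size))
    for k, fc in enumerate(cutoffs):
        sos = sps.butter(2, fc, btype="lowpass", fs=x.fs, output="sos")
        smooth = sps.sosfiltfilt(sos, x.samples)
        stack[k] = np.abs(np.gradient(np.gradient(smooth)))
    return stack, cutoffs


def detect_qrs(x: SampledSignal, cfg: DetectorConfig | None = None) -> QrsAnnotation:
    """Detect QRS events by multiscale structural-intensity evidence.

    Returns an empty annotation (with zero beats) when no suprathreshold
    evidence peak exists.
    """
    cfg = cfg or DetectorConfig()
    if x.duration < 2.0:
        raise ValueError("detection requires a record of at least 2 s")
    stack, _ = _scale_stack(x, cfg)
    fs = x.fs
    link_win = int(round(0.05 * fs))  # extrema-line continuity tolerance

    # peaks per scale, coarsest (lowest cut-off) first
    per_scale = []
    for row in stack:
        pk, _ = sps.find_peaks(row, distance=max(1, int(0.1 * fs)))
        per_scale.append(pk)

    # extrema lines: seed at the coarsest scale, follow the nearest peak in
    # each finer scale; score = persistence count weighted by mean amplitude
    lines = []  # (position at finest linked scale, score)
    for p0 in per_scale[0]:
        pos = p0
        persistence = 1
        amp_sum = stack[0][p0]
        for s in range(1, len(per_scale)):
            cand = per_scale[s]
            if cand.size == 0:
                break
            j = np.argmin(np.abs(cand - pos))
            if abs(int(cand[j]) - int(pos)) > link_win:
                break
            pos = int(cand[j])
            persistence += 1
            amp_sum += stack[s][cand[j]]
        # persistence-weighted mean amplitude == summed amplitude along the line
        lines.append((pos, amp_sum))

    if not lines:
        return QrsAnnotation(np.array([]), fs)
    positions = np.array([p for p, _ in lines])
    scores = np.array([s for _, s in lines])
    thr = cfg.threshold_fraction * scores.max()
    keep = scores >= thr
    positions, scores = positions[keep], scores[keep]

    # refractory: greedy by score, drop candidates within the minimum RR
    order = np.argsort(scores)[::-1]
    accepted: list[int] = []
    min_gap = int(round(cfg.refractory * fs))
    for idx in order:
        p = positions[idx]
        if all(abs(p - q) >= min_gap for q in accepted):
            accepted.append(int(p))
    accepted.sort()
    ann = QrsAnnotation(np.array(accepted, dtype=float) / fs, fs)
    if cfg.refine and len(ann) >= 2:
        ann = refine_alignment(x, ann)
    return ann


def refine_alignment(
    x: SampledSignal, qrs: QrsAnnotation, search: float = 0.025, half_window: float = 0.1
) -> QrsAnnotation:
    """Refine beat times by cross-correlation with the running average beat.

    Each beat's local segment (±``half_window`` s) is aligned to the running
    mean of previously refined segments, searching lags within ±``search`` s.
    Beats are never reordered and never moved beyond the search window; a
    single beat or a degenerate (flat) segment is left unchanged.
    """
    if len(qrs) < 2:
        return qrs
    fs = x.fs
    hw = int(round(half_window * fs))
    sw = int(round(search * fs))
    n = x.samples.size
    refined = []
    template: np.ndarray | None = None
    count = 0
    for t in qrs.beat_times:
        c = int(round(t * fs))
        lo, hi = c - hw, c + hw + 1
        if lo - sw < 0 or hi + sw > n:
            refined.append(t)
            continue
        seg = x.samples[lo:hi]
        if template is None:
            template = seg.astype(float).copy()
            count = 1
            refined.append(t)
            continue
        tpl = template - template.mean()
        if np.ptp(seg) == 0 or np.ptp(tpl) == 0:
            refined.append(t)
            continue
        lags = np.arange(-sw, sw + 1)
        scores = np.empty(lags.size)
        for i, lag in enumerate(lags):
            s = x.samples[lo + lag : hi + lag]
            s = s - s.mean()
            scores[i] = float(np.dot(s, tpl))
        best = int(lags[np.argmax(scores)])
        new_c = c + best
        refined.append(new_c / fs)
        seg_new = x.samples[new_c - hw : new_c + hw + 1]
        template = (template * count + seg_new) / (count + 1)
        count += 1
    refined_arr = np.array(refined)
    # keep ordering: fall back to the raw time if a shift would reorder
    for i in range(1, refined_arr.size):
        if refined_arr[i] <= refined_arr[i - 1]:
            refined_arr[i] = qrs.beat_times[i]
    return QrsAnnotation(refined_arr, fs)
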