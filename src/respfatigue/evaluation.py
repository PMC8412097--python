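"""Evaluation criteria for processing-chain variants and comparison statistics.

Three criteria score a chain (artifact removal + fatigue detection) on
normalized fatigue series:

γA
    RMS deviation of the 60%-MVC fatigue series from the uncontaminated
    reference over the first minute (lower is better).
γB
    Two-sample Kolmogorov–Smirnov distance between fatigue values of the
    20% and 60% MVC cases over the last 15 s — separability of fatigued
    and non-fatigued states (higher is better).
γC
    Coefficient of determination R² of a line fitted to the 60%-MVC series
    over the first minute — ruggedness of the fatigue trajectory (higher is
    better).

A Friedman test with rank-sum group selection and Holm-adjusted 1-to-N
pairwise comparisons ranks chain variants across subjects/seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fatigue import FatigueSeries
from .qrs import QrsAnnotation
from .removal import GATE_POST, GATE_PRE
from .signal import SampledSignal


@dataclass
class EvalResult:
    """The criterion triple for one chain variant at one EMG level."""

    gamma_a: float
    gamma_b: float
    gamma_c: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.gamma_a) and self.gamma_a < 0:
            raise ValueError("gamma_a is an RMS value and must be >= 0")
        if np.isfinite(self.gamma_b) and not (0 <= self.gamma_b <= 1):
            raise ValueError("gamma_b is a KS distance in [0, 1]")


def _aligned(a: FatigueSeries, b: FatigueSeries) -> tuple[np.ndarray, np.ndarray]:
    if a.times.size != b.times.size or not np.allclose(a.times, b.times):
        raise ValueError("series grids are misaligned")
    m = np.isfinite(a.values) & np.isfinite(b.values)
    if not np.any(m):
        raise ValueError("no overlapping finite values")
    return a.values[m], b.values[m]


def gamma_a(phi60_hat: FatigueSeries, xi60_hat: FatigueSeries, t_max: float = 60.0) -> float:
    """RMS difference between normalized series over (0, t_max] s."""
    va, vb = _aligned(phi60_hat, xi60_hat)
    t = phi60_hat.times[np.isfinite(phi60_hat.values) & np.isfinite(xi60_hat.values)]
    sel = (t > 0) & (t <= t_max)
    d = va[sel] - vb[sel]
    if d.size == 0:
        raise ValueError("no samples in the evaluation window")
    return float(np.sqrt(np.mean(d**2)))


def gamma_b(
    phi20_hat: FatigueSeries, phi60_hat: FatigueSeries, t_lo: float = 45.0, t_hi: float = 60.0
) -> float:
    """KS distance between the 20% and 60% MVC fatigue values on (45, 60] s."""
    v20 = phi20_hat.window(t_lo, t_hi)
    v60 = phi60_hat.window(t_lo, t_hi)
    if v20.size == 0 or v60.size == 0:
        raise ValueError("empty value vectors in the separability window")
    return float(stats.ks_2samp(v20, v60).statistic)


def ks_distance_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive-threshold two-sample KS statistic (independent oracle).

    Evaluates the empirical-CDF gap at every pooled sample value.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    best = 0.0
    for thr in np.concatenate([a, b]):
        fa = np.sum(a <= thr) / a.size
        fb = np.sum(b <= thr) / b.size
        best = max(best, abs(fa - fb))
    return float(best)


def gamma_c(phi60_hat: FatigueSeries, t_max: float = 60.0) -> float:
    """R² of an OLS line fitted to the series over (0, t_max) s."""
    m = (phi60_hat.times > 0) & (phi60_hat.times < t_max) & np.isfinite(phi60_hat.values)
    if np.sum(m) < 3:
        raise ValueError("need at least 3 points for the regression")
    res = stats.linregress(phi60_hat.times[m], phi60_hat.values[m])
    return float(res.rvalue**2)


def evaluate_chain(
    phi60_hat: FatigueSeries,
    phi20_hat: FatigueSeries,
    xi60_hat: FatigueSeries,
    labels: dict | None = None,
) -> EvalResult:
    """Convenience wrapper computing the (γA, γB, γC) triple."""
    return EvalResult(
        gamma_a(phi60_hat, xi60_hat),
        gamma_b(phi20_hat, phi60_hat),
        gamma_c(phi60_hat),
        labels or {},
    )


def residual_qrs_fraction(
    before: SampledSignal,
    after: SampledSignal,
    qrs: QrsAnnotation,
    emg_component: SampledSignal | None = None,
) -> float:
    """Fraction of the QRS artifact surviving a removal method.

    Within each [−0.05, +0.1) s QRS window the residual artifact (output
    minus the known EMG component) is compared in RMS to the artifact before
    removal, and the per-beat ratios are averaged.  With no EMG component
    given, the input is treated as pure artifact.  On synthetic data the
    generator supplies the ground-truth EMG component; the metric is not a
    certified reproduction of any published residual-fraction definition.
    """
    if len(before) != len(after):
        raise ValueError("records are misaligned")
    if len(qrs) == 0:
        raise ValueError("at least one beat required")
    emg = np.zeros(len(before)) if emg_component is None else emg_component.samples
    art_before = before.samples - emg
    art_after = after.samples - emg
    fs = before.fs
    ratios = []
    for t in qrs.beat_times:
        lo = max(int(round((t - GATE_PRE) * fs)), 0)
        hi = min(int(round((t + GATE_POST) * fs)), len(before))
        if hi - lo < 2:
            continue
        denom = float(np.sqrt(np.mean(art_before[lo:hi] ** 2)))
        if denom == 0:
            continue
        num = float(np.sqrt(np.mean(art_after[lo:hi] ** 2)))
        ratios.append(num / denom)
    if not ratios:
        raise ValueError("no usable beat windows")
    return float(np.mean(ratios))


def compare_groups(
    table: np.ndarray, group_names: list[str] | None = None, better: str = "lower"
) -> dict:
    """Friedman test with rank-sum best-group selection and Holm adjustment.

    ``table`` has shape (blocks, groups) — complete blocks (one value per
    group for every subject/seed).  The best group (smallest rank sum for
    ``better='lower'``, largest otherwise) is compared 1-to-N against the
    others with Wilcoxon signed-rank tests, Holm-adjusted at α = 0.05.
    Ties get mid-ranks.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need a (blocks, groups) table with >= 2 groups")
    if not np.all(np.isfinite(table)):
        raise ValueError("incomplete blocks: table contains non-finite values")
    n_blocks, n_groups = table.shape
    names = group_names or [f"g{i}" for i in range(n_groups)]
    ranks = np.apply_along_axis(stats.rankdata, 1, table)  # mid-rank ties
    rank_sums = ranks.sum(axis=0)
    if np.allclose(table, table[:, [0]]):
        statistic, pvalue = 0.0, 1.0
    else:
        statistic, pvalue = stats.friedmanchisquare(*table.T)
    best = int(np.argmin(rank_sums) if better == "lower" else np.argmax(rank_sums))
    raw_p, others = [], []
    for j in range(n_groups):
        if j == best:
            continue
        others.append(names[j])
        if np.allclose(table[:, best], table[:, j]):
            raw_p.append(1.0)
        else:
            raw_p.append(float(stats.wilcoxon(table[:, best], table[:, j]).pvalue))
    if raw_p:
        reject, adj_p, _, _ = multipletests(raw_p, alpha=0.05, method="holm")
    else:
        reject, adj_p = np.array([]), np.array([])
    return {
        "statistic": float(statistic),
        "pvalue": float(pvalue),
        "rank_sums": dict(zip(names, rank_sums.tolist())),
        "best": names[best],
        "pairwise": {
            o: {"p_holm": float(p), "significant": bool(r)}
            for o, p, r in zip(others, adj_p, reject)
        },
    }
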