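"""Distribution summaries, ROC/Youden cutoffs and nonparametric tests.

Shape-factor distributions are summarised as relative-frequency histograms
over [0, 1] with 0.05-wide bins, with mean, median, mode (modal bin
center), SD and IQR.  Classification of "round" capillaries uses inclusive
cutoffs (roundness >= 0.47, circularity >= 0.60 per capillary; mean
circularity >= 0.51 per region), the thresholds originally chosen by the
Youden index of an ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

@dataclass
class DistributionHistogram:
    bin_width: float
    edges: np.ndarray
    counts: np.ndarray
    rel_freq: np.ndarray
    n: int
    mean: float
    median: float
    mode: float      # center of the most populated bin (ties -> lowest bin)
    sd: float
    iqr: float


def summarize_distribution(values: Iterable[float],
                           bin_width: float = 0.05) -> DistributionHistogram:
    """Histogram over [0, 1] plus the five summary statistics.

    Bins are half-open [lo, hi) with the last bin closed at 1.0 (numpy's
    convention).  ``bin_width`` must divide 1 evenly.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("values must lie in [0, 1]")
    nbins = round(1.0 / bin_width)
    if abs(nbins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 1 evenly")
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(v, bins=edges)
    modal = int(np.argmax(counts))  # argmax takes the first (lowest) bin on ties
    return DistributionHistogram(
        bin_width=bin_width,
        edges=edges,
        counts=counts,
        rel_freq=counts / v.size,
        n=int(v.size),
        mean=float(v.mean()),
        median=float(np.median(v)),
        mode=float((edges[modal] + edges[modal + 1]) / 2.0),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        iqr=float(np.percentile(v, 75) - np.percentile(v, 25)),
    )


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray       # candidate cutoffs, ascending
    sensitivity: np.ndarray      # P(score >= t | positive)
    specificity: np.ndarray      # P(score <  t | negative)
    auc: float
    youden_j: float
    optimal_cutoff: float


def roc_youden(scores: Sequence[float], labels: Sequence[bool | int]) -> RocResult:
    """Empirical ROC over all distinct score thresholds, AUC and Youden cutoff.

    The classifier is ``score >= t -> positive``.  AUC is the trapezoidal
    area, equal to the probability that a random positive outscores a random
    negative with ties counted 1/2.  The optimal cutoff maximises Youden's
    J = sensitivity + specificity - 1; ties go to the lower cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D sequences")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    # thresholds: each unique score, plus one above the maximum (nothing positive)
    thr = np.concatenate([uniq, [uniq[-1] + 1.0]])
    sens = np.array([(s[y] >= t).mean() for t in thr])
    spec = np.array([(s[~y] < t).mean() for t in thr])
    # ROC curve: thresholds ascending -> (FPR, TPR) descending from (1,1) to
    # (0,0); reverse for the trapezoid.  Endpoints are included by
    # construction (t = min score and t > max score).
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # thresholds ascending; argmax -> lowest cutoff on ties
    return RocResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_j=float(j[best]),
        optimal_cutoff=float(thr[best]),
    )


def classify_round(
    values: Sequence[float],
    cutoff: float,
) -> tuple[int, float | None]:
    """Count and fraction of values at or above the cutoff (inclusive).

    For the per-capillary rule pass capillary descriptor values; for the
    region-mean rule pass per-region mean values.  Empty input yields count
    0 and fraction ``None``.
    """
    if not (0 <= cutoff <= 1):
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    v = np.asarray(list(values), dtype=float)
    n_round = int((v >= cutoff).sum())
    return n_round, (n_round / v.size) if v.size else None


# ---------------------------------------------------------------------------
# correlation and group tests
# ---------------------------------------------------------------------------

def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with two-tailed p value.

    Intended for ordinal covariates such as GFR categories G1–G5 or IFTA
    grades 0–3 against shape descriptors.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired data with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has no defined rank correlation")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class GroupTestReport:
    test: str                      # "mann-whitney" | "kruskal-wallis"
    statistic: float
    p_value: float
    posthoc: "pd.DataFrame | None" = None  # Dunn z tests, Bonferroni-adjusted


def _dunn_bonferroni(groups: Sequence[np.ndarray]) -> "pd.DataFrame":
    """Dunn's pairwise z tests on pooled midranks with Bonferroni correction."""
    import pandas as pd

    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    sizes = [g.size for g in groups]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    k = len(groups)
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_i": i, "group_j": j, "z": z,
                         "p_raw": p, "p_bonferroni": min(p * m, 1.0)})
    return pd.DataFrame(rows)


def group_tests(groups: Sequence[Sequence[float]]) -> GroupTestReport:
    """Two-sided Mann–Whitney U (2 groups) or Kruskal–Wallis H with
    Dunn-Bonferroni post hoc tests (>2 groups).

    Mann–Whitney uses the exact null distribution for small samples without
    ties and the normal approximation otherwise (scipy's default policy).
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if len(arrays) == 2:
        res = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return GroupTestReport("mann-whitney", float(res.statistic),
                               float(res.pvalue))
    res = sps.kruskal(*arrays)
    return GroupTestReport("kruskal-wallis", float(res.statistic),
                           float(res.pvalue), posthoc=_dunn_bonferroni(arrays))
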