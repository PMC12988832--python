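"""Nonparametric comparison of image-quality metrics across time points.

The procedure: Shapiro--Wilk normality per group, a rank-based
Kruskal--Wallis omnibus test across groups (chi-square reference with
k-1 degrees of freedom, tie-corrected), and Dunn's z post-hoc test for
pairwise differences, unadjusted by default with an optional Bonferroni
mode.  Boxplot summaries follow the Tukey convention: whiskers extend to
the most extreme points within 1.5 IQR of the quartiles; points beyond
are outliers.  Quartiles use linear interpolation between closest ranks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "shapiro_wilk",
    "kruskal_wallis",
    "dunn_posthoc",
    "boxplot_summary",
    "significance_stars",
    "compare_groups",
]

ALPHA = 0.05


def shapiro_wilk(samples) -> tuple[float, float]:
    """Shapiro--Wilk W statistic and p-value for one sample set."""
    x = np.asarray(samples, dtype=float).ravel()
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality is undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _check_groups(groups: dict) -> dict[float, np.ndarray]:
    clean = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(list(clean.values()))
    if np.ptp(pooled) == 0:
        raise ValueError("no rank variation: all values identical across groups")
    return clean


def kruskal_wallis(groups: dict) -> tuple[float, float]:
    """Tie-corrected Kruskal--Wallis H and chi-square p across groups.

    ``groups`` maps a label (e.g. minutes post-injection) to a 1-D sample
    array.
    """
    clean = _check_groups(groups)
    if sum(len(v) for v in clean.values()) < 5:
        raise ValueError("total sample size must be >= 5")
    h, p = sps.kruskal(*clean.values())
    return float(h), float(p)


def dunn_posthoc(
    groups: dict, adjust: str = "none"
) -> list[dict]:
    """Dunn's z test for every group pair.

    For pair (i, j): ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 -
    T/(12(N-1))) * (1/n_i + 1/n_j))`` where ``T = sum(t^3 - t)`` over tie
    groups and Rbar are mean ranks of the pooled sample; two-sided p from
    the standard normal.  ``adjust`` is ``"none"`` (default) or
    ``"bonferroni"``.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError("adjust must be 'none' or 'bonferroni'")
    clean = _check_groups(groups)
    labels = list(clean.keys())
    pooled = np.concatenate([clean[k] for k in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)

    mean_ranks: dict = {}
    start = 0
    for k in labels:
        n = clean[k].size
        mean_ranks[k] = ranks[start : start + n].mean()
        start += n

    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    n_pairs = len(labels) * (len(labels) - 1) // 2
    out = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_term * (1.0 / clean[a].size + 1.0 / clean[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * n_pairs)
        out.append(
            {
                "group_a": a,
                "group_b": b,
                "z": float(z),
                "p": float(p),
                "stars": significance_stars(float(p)),
            }
        )
    return out


def boxplot_summary(samples) -> dict:
    """Median, quartiles, Tukey whiskers, and outliers of one sample set."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": outliers.tolist(),
        "n": int(x.size),
    }


def significance_stars(p: float) -> str:
    """Most extreme applicable label: ns, *, **, ***, **** for p below
    0.05, 0.01, 0.001, 0.0001 (strict inequalities)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    """Full comparison report for one metric across time points."""

    metric: str
    normality: dict = field(default_factory=dict)  # label -> {"W", "p"}
    kruskal_h: float = float("nan")
    kruskal_p: float = float("nan")
    pairwise: list = field(default_factory=list)
    box_summaries: dict = field(default_factory=dict)
    alpha: float = ALPHA

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "alpha": self.alpha,
            "normality": self.normality,
            "kruskal_wallis": {"H": self.kruskal_h, "p": self.kruskal_p},
            "pairwise": self.pairwise,
            "boxplot_summaries": self.box_summaries,
        }


def compare_groups(
    groups: dict, metric: str = "metric", adjust: str = "none"
) -> ComparisonResult:
    """Run the full procedure (normality, omnibus, post-hoc, box
    summaries) on one metric's grouped samples."""
    clean = _check_groups(groups)
    for k, v in clean.items():
        if v.size < 3:
            raise ValueError(f"group {k}: need n >= 3")
    res = ComparisonResult(metric=metric)
    for k, v in clean.items():
        try:
            w, p = shapiro_wilk(v)
            res.normality[k] = {"W": w, "p": p}
        except ValueError:
            res.normality[k] = {"W": float("nan"), "p": float("nan")}
        res.box_summaries[k] = boxplot_summary(v)
    res.kruskal_h, res.kruskal_p = kruskal_wallis(clean)
    res.pairwise = dunn_posthoc(clean, adjust=adjust)
    return res
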