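"""Virtual-screening performance metrics: enrichment factors and ROC/AUC.

The enrichment factor measures how much better than random a selection
protocol concentrates actives:

    EF = [t_p / (t_p + f_n)] * (NC_tot / NC)

where t_p actives are retrieved, f_n discarded, NC compounds are
retrieved in total out of a library of NC_tot.  Selecting the whole
library gives EF = 1 exactly; retrieving only actives gives the maximum
attainable EF, min(NC, A)/A * NC_tot/NC — hence the familiar maxima of
100, 20 and 10 for EF at the top 1%, 5% and 10% of a library with at
least that many actives.  EFs are often quoted as a percentage of that
maximum so different retrieval sizes are comparable.

ROC curves come in two flavours here: from continuous scores (standard
threshold sweep, delegated to scikit-learn) and from discrete consensus
levels, where each level k contributes one vertex (TPR, FPR = fractions
of actives/decoys at level ≥ k) and the trapezoidal area equals the
tie-corrected Mann-Whitney statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "EnrichmentCounts",
    "RocCurve",
    "enrichment_factor",
    "max_enrichment_factor",
    "percent_of_max_ef",
    "ef_at_fraction",
    "roc_from_levels",
    "roc_from_scores",
]


class MetricError(ValueError):
    """Raised on invalid metric inputs."""


@dataclass(frozen=True)
class EnrichmentCounts:
    """Retrieval bookkeeping for one selection: t_p actives retrieved,
    f_n actives discarded, NC compounds retrieved, NC_tot library size."""

    t_p: int
    f_n: int
    n_retrieved: int
    n_total: int

    def __post_init__(self):
        if self.t_p < 0 or self.f_n < 0:
            raise MetricError("counts must be non-negative")
        if self.t_p > self.n_retrieved:
            raise MetricError("t_p cannot exceed the number retrieved")
        if self.n_retrieved > self.n_total:
            raise MetricError("cannot retrieve more than the library size")

    @property
    def n_actives(self) -> int:
        return self.t_p + self.f_n


def enrichment_factor(c: EnrichmentCounts) -> float:
    """EF = [t_p/(t_p+f_n)] × (NC_tot/NC)."""
    if c.n_retrieved == 0:
        raise MetricError("no compounds retrieved (NC = 0)")
    if c.n_actives == 0:
        raise MetricError("no actives in the library (t_p + f_n = 0)")
    return (c.t_p / c.n_actives) * (c.n_total / c.n_retrieved)


def max_enrichment_factor(n_actives: int, n_retrieved: int, n_total: int) -> float:
    """EF attained when the retrieved set is maximally active:
    (min(NC, A)/A) × (NC_tot/NC)."""
    if n_retrieved == 0:
        raise MetricError("no compounds retrieved (NC = 0)")
    if n_actives == 0:
        raise MetricError("no actives in the library")
    return (min(n_retrieved, n_actives) / n_actives) * (n_total / n_retrieved)


def percent_of_max_ef(c: EnrichmentCounts) -> float:
    """The EF as a percentage of the maximum EF reachable at this
    retrieval size."""
    return 100.0 * enrichment_factor(c) / max_enrichment_factor(
        c.n_actives, c.n_retrieved, c.n_total)


def _order_ranking(
    labels: np.ndarray,
    scores: np.ndarray,
    score_direction: str,
    tie_policy: str,
) -> np.ndarray:
    """Return label array sorted best-score-first; within a tied score
    block, the pessimistic policy places actives after decoys (so a tied
    block straddling a cutoff never flatters the selection), optimistic
    the reverse."""
    if tie_policy not in ("pessimistic", "optimistic"):
        raise MetricError(f"unknown tie policy {tie_policy!r}")
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if score_direction == "lower-better":
        s = -s
    elif score_direction != "higher-better":
        raise MetricError(f"invalid score_direction {score_direction!r}")
    tie_key = lab if tie_policy == "pessimistic" else -lab
    order = np.lexsort((tie_key, -s))
    return lab[order]


def ef_at_fraction(
    labels,
    scores,
    fraction: float,
    score_direction: str = "higher-better",
    tie_policy: str = "pessimistic",
) -> tuple[float, float]:
    """EF over the top ``fraction`` of a scored library, plus the
    percentage of the maximum EF at that cut.

    The cut retains NC = floor(fraction × NC_tot) compounds; ties
    straddling the cut are resolved by ``tie_policy`` (default
    pessimistic: actives sort after decoys within a tied block).
    Returns (EF, percent-of-max).
    """
    lab = np.asarray(labels, dtype=int)
    if lab.size == 0:
        raise MetricError("empty ranking")
    n_total = lab.size
    nc = int(np.floor(fraction * n_total))
    if nc < 1:
        raise MetricError(f"fraction {fraction} retains no compounds from {n_total}")
    ordered = _order_ranking(lab, scores, score_direction, tie_policy)
    n_actives = int(lab.sum())
    t_p = int(ordered[:nc].sum())
    c = EnrichmentCounts(t_p, n_actives - t_p, nc, n_total)
    return enrichment_factor(c), percent_of_max_ef(c)


@dataclass
class RocCurve:
    """ROC vertices from (0,0) to (1,1) with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self):
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if np.any(np.diff(self.fpr) < -1e-12) or np.any(np.diff(self.tpr) < -1e-12):
            raise MetricError("ROC points must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})

    def plot(self, ax=None, **kwargs):
        """Plot the curve (diagonal shown dashed for reference)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, **kwargs)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"ROC (AUC = {self.auc:.2f})")
        return ax


def roc_from_levels(level_counts: pd.DataFrame) -> RocCurve:
    """ROC from cumulative consensus-level counts.

    ``level_counts`` holds one row per level k with cumulative columns
    ``actives`` and ``decoys`` (compounds at level ≥ k); row k=1 must be
    the library totals.  Each threshold contributes one vertex (FPR, TPR)
    = (decoys≥k / D, actives≥k / A), descending k, prepended with (0,0);
    the trapezoidal area equals the Mann-Whitney statistic with ties
    counted ½.
    """
    df = pd.DataFrame(level_counts).sort_values("level").reset_index(drop=True)
    for col in ("actives", "decoys"):
        vals = df[col].to_numpy()
        if np.any(np.diff(vals) > 0):
            raise MetricError(f"cumulative {col} counts must be non-increasing in level")
    A = int(df["actives"].iloc[0])
    D = int(df["decoys"].iloc[0])
    if A == 0 or D == 0:
        raise MetricError("need both actives and decoys")
    # descending k: strictest threshold first
    tpr = [0.0] + [a / A for a in df["actives"].to_numpy()[::-1]]
    fpr = [0.0] + [d / D for d in df["decoys"].to_numpy()[::-1]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(np.array(fpr), np.array(tpr), auc)


def roc_from_scores(labels, scores, score_direction: str = "higher-better") -> RocCurve:
    """Standard ROC over score thresholds with tie-corrected trapezoidal
    AUC (scikit-learn backend)."""
    lab = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise MetricError("scores must be finite")
    if len(np.unique(lab)) < 2:
        raise MetricError("need both actives and decoys")
    if score_direction == "lower-better":
        s = -s
    elif score_direction != "higher-better":
        raise MetricError(f"invalid score_direction {score_direction!r}")
    fpr, tpr, _ = roc_curve(lab, s)
    auc = float(roc_auc_score(lab, s))
    return RocCurve(fpr, tpr, auc)
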