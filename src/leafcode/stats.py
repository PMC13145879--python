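"""Performance statistics: per-class metrics, one-way ANOVA with
effect sizes, Tukey HSD pairwise comparisons, t-based confidence
intervals and confusion-matrix normalization.

The ANOVA unit throughout the pipeline is the per-fold weighted
F-measure (10 replicates per algorithm and surface), which is what a
t-based confidence interval on a mean F-measure presupposes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ConfusionMatrix:
    """Class-ordered integer counts, rows = true class."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConfusionMatrix":
        return cls(labels=list(df.index), counts=df.to_numpy())

    @property
    def row_pct(self) -> np.ndarray:
        return normalize_confusion(self)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float
    eta2: float
    omega2: float


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Precision, recall and F-measure per class; zero denominators
    yield 0 rather than an exception."""
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return pd.DataFrame(
        {
            "class": cm.labels,
            "precision": prec,
            "recall": rec,
            "f": f,
            "support": counts.sum(axis=1),
        }
    )


def summary_metrics(
    cm: ConfusionMatrix,
    y_true: np.ndarray | None = None,
    proba: np.ndarray | None = None,
) -> dict[str, float]:
    """Accuracy, support-weighted F and (when scores are given)
    support-weighted one-vs-rest ROC area."""
    per = per_class_metrics(cm)
    total = cm.counts.sum()
    out = {
        "accuracy": float(np.trace(cm.counts) / total),
        "weighted_f": float(np.average(per["f"], weights=per["support"])),
    }
    if proba is not None and y_true is not None:
        from .cv import weighted_ovr_auc

        out["roc_auc"] = weighted_ovr_auc(
            np.asarray(y_true), np.asarray(proba), np.array(cm.labels)
        )
    else:
        warnings.warn("probability scores absent; ROC area omitted", stacklevel=2)
    return out


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way decomposition with eta- and omega-squared.

    eta2 = SSB/SST; omega2 = (SSB - df_b*MSW) / (SST + MSW), floored
    at 0.  All values identical across groups gives F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    sst = ssb + ssw
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    if ssw <= 0 and ssb <= 0:
        return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, 0.0, 0.0, 0.0)
    msw = ssw / df_w
    if msw == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / df_b) / msw
        p = float(sps.f.sf(f_stat, df_b, df_w))
    eta2 = ssb / sst if sst > 0 else 0.0
    omega2 = max((ssb - df_b * msw) / (sst + msw), 0.0) if sst + msw > 0 else 0.0
    return AnovaResult(
        F=float(f_stat), df_between=df_b, df_within=df_w, p=p,
        ss_between=float(ssb), ss_within=float(ssw),
        eta2=float(eta2), omega2=float(omega2),
    )


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey(-Kramer) pairwise comparisons.

    q = |mean_i - mean_j| / sqrt(MSW / n_h) with the harmonic mean
    n_h of the pair sizes; adjusted p from the studentized-range
    distribution with K groups and the ANOVA within-groups df.
    Returns one row per pair with the 95% family-wise interval.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    res = anova_oneway(arrays)
    msw = res.ss_within / res.df_within
    k = len(names)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        gi, gj = arrays[i], arrays[j]
        diff = float(gi.mean() - gj.mean())
        n_h = 2.0 / (1.0 / len(gi) + 1.0 / len(gj))
        se = np.sqrt(msw / n_h)
        if se == 0:
            q = 0.0 if diff == 0 else float("inf")
        else:
            q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, res.df_within)) if np.isfinite(q) else 0.0
        q_crit = float(sps.studentized_range.ppf(0.95, k, res.df_within))
        half = q_crit * se
        rows.append(
            {
                "group_1": a, "group_2": b, "mean_diff": diff, "q": float(q),
                "p_adj": min(max(p_adj, 0.0), 1.0),
                "ci_low": diff - half, "ci_high": diff + half,
            }
        )
    return pd.DataFrame(rows)


def t_confidence_interval(
    values: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """(mean, low, high) with a Student-t interval using the sample
    standard deviation."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values for a t interval")
    mean = float(values.mean())
    s = float(values.std(ddof=1))
    half = float(sps.t.ppf((1 + level) / 2, n - 1)) * s / np.sqrt(n)
    return mean, mean - half, mean + half


def normalize_confusion(cm: ConfusionMatrix) -> np.ndarray:
    """Row-percentage matrix (each nonempty row sums to 100); empty
    rows become zeros with a warning.  Full precision is kept —
    rounding to integers happens only at render time."""
    counts = cm.counts.astype(float)
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        warnings.warn("confusion matrix has empty rows", stacklevel=2)
    safe = np.where(row_sums > 0, row_sums, 1.0)
    return counts / safe[:, None] * 100.0
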