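"""Cross-metric comparison within and across cohorts.

Spearman correlation matrices among the six CIN metrics, per-cohort and
pooled; distribution summaries of tumor vs. non-tumor scores; and a
deterministic complete-linkage/Euclidean leaf order for heatmap export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .metrics import METRIC_NAMES
from .seg_io import TumorClass

logger = logging.getLogger(__name__)


def _class_str(v: object) -> str:
    return v.value if isinstance(v, TumorClass) else str(v)


class UndefinedCorrelationError(ValueError):
    """Spearman correlation is undefined (length mismatch or constant vector)."""


class InsufficientDataError(ValueError):
    """Too few samples to compute a cohort's correlation matrix."""


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal Spearman matrix over the six metrics."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        assert v.shape == (len(self.labels), len(self.labels))
        assert np.allclose(v, v.T, atol=1e-12), "correlation matrix must be symmetric"
        assert np.allclose(np.diag(v), 1.0, atol=1e-12), "diagonal must be 1"
        assert (np.abs(v) <= 1 + 1e-12).all(), "entries must lie in [-1, 1]"
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self, cohort: str = "ALL") -> pd.DataFrame:
        """Long format: one row per (metric_a, metric_b) pair."""
        rows = [
            {"cancer_type": cohort, "metric_a": a, "metric_b": b, "rho": self.values[i, j]}
            for i, a in enumerate(self.labels)
            for j, b in enumerate(self.labels)
        ]
        return pd.DataFrame(rows)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Requires equal lengths >= 3 and at least two distinct values per vector.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise UndefinedCorrelationError("need two equal-length vectors of length >= 3")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise UndefinedCorrelationError("constant vector: rank correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def metric_correlation_matrix(scores: pd.DataFrame, metrics=METRIC_NAMES) -> CorrelationMatrix:
    """Pairwise Spearman matrix over metric columns of a scores table."""
    if len(scores) < 3:
        raise InsufficientDataError(f"need >= 3 samples, got {len(scores)}")
    m = len(metrics)
    vals = np.eye(m)
    cols = [scores[name].to_numpy(float) for name in metrics]
    for name, c in zip(metrics, cols):
        if len(np.unique(c)) < 2:
            raise UndefinedCorrelationError(f"metric {name!r} is constant in this cohort")
    for i in range(m):
        for j in range(i + 1, m):
            vals[i, j] = vals[j, i] = spearman_rho(cols[i], cols[j])
    return CorrelationMatrix(labels=list(metrics), values=vals)


def per_cohort_correlations(
    scores: pd.DataFrame, metrics=METRIC_NAMES, cohort_col: str = "cancer_type"
) -> dict[str, CorrelationMatrix]:
    """One Spearman matrix per cohort, restricted to tumor samples.

    ``scores`` carries metric columns plus ``cancer_type`` and ``sample_class``
    (a :class:`~cinscore.seg_io.TumorClass` value or its string). Cohorts with
    fewer than 3 tumor samples, or with a constant metric, are skipped with a
    warning.
    """
    tumor = scores
    if "sample_class" in scores.columns:
        tumor = scores[scores["sample_class"].map(_class_str) == TumorClass.TUMOR.value]
    out: dict[str, CorrelationMatrix] = {}
    for cohort, sub in tumor.groupby(cohort_col, sort=True):
        try:
            out[str(cohort)] = metric_correlation_matrix(sub, metrics=metrics)
        except (InsufficientDataError, UndefinedCorrelationError) as exc:
            logger.warning("skipping cohort %s: %s", cohort, exc)
    return out


def cluster_order(matrix) -> np.ndarray:
    """Leaf order of complete-linkage hierarchical clustering (Euclidean).

    Deterministic for a given input: scipy's linkage resolves distance ties by
    the lower candidate index. Returns a permutation of row indices.
    """
    x = np.asarray(matrix, float)
    if x.ndim == 1:
        x = x[:, None]
    if len(x) < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.isfinite(x).all():
        raise ValueError("non-finite entries in clustering input")
    z = hierarchy.linkage(x, method="complete", metric="euclidean")
    return np.asarray(hierarchy.leaves_list(z), int)


def summarize_distributions(scores: pd.DataFrame, metrics=METRIC_NAMES) -> pd.DataFrame:
    """Count/median/quartile summary per (cohort, metric, tumor class).

    ``scores`` carries metric columns plus ``cancer_type`` and ``sample_class``;
    samples of UNKNOWN class are excluded. Quartiles use linear interpolation.
    """
    keep = scores.assign(sample_class=scores["sample_class"].map(_class_str))
    keep = keep[keep["sample_class"] != TumorClass.UNKNOWN.value]
    long = keep.melt(
        id_vars=["cancer_type", "sample_class"],
        value_vars=list(metrics),
        var_name="metric",
        value_name="value",
    )
    if long.empty:
        return pd.DataFrame(columns=["cancer_type", "metric", "sample_class", "n", "median", "q25", "q75"])
    g = long.groupby(["cancer_type", "metric", "sample_class"], sort=True)["value"]
    out = g.agg(
        n="size",
        median="median",
        q25=lambda v: v.quantile(0.25),
        q75=lambda v: v.quantile(0.75),
    ).reset_index()
    return out
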