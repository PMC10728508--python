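"""Rank-based association of CIN metrics with clinical contrasts.

Each metric is compared between two clinical groups per cohort with the
Mann-Whitney (Wilcoxon rank-sum) test: tumor stage T4 vs T1, metastasis
M1 vs M0, nodal involvement N1 vs N0, and male vs female. P-values are
Bonferroni-corrected within the family of cohorts tested for a given
(metric, contrast), and cohorts are ranked by adjusted p per panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES
from .seg_io import TumorClass

logger = logging.getLogger(__name__)

#: Cohorts occurring predominantly in one biological sex, excluded from the
#: sex comparison by default.
DEFAULT_SINGLE_SEX_COHORTS: frozenset[str] = frozenset(
    {"OV", "PRAD", "UCEC", "UCS", "TGCT", "CESC"}
)


@dataclass(frozen=True)
class GroupComparison:
    """A two-group clinical contrast: group a vs. group b on one column."""

    contrast: str  # "T4_vs_T1" | "M1_vs_M0" | "N1_vs_N0" | "sex"
    column: str  # clinical column holding the group labels
    group_a_label: str
    group_b_label: str


#: The four standard contrasts. Group a is the higher-stage (or male) group,
#: so a positive direction means higher CIN with advanced stage / in males.
CONTRASTS: dict[str, GroupComparison] = {
    "T4_vs_T1": GroupComparison("T4_vs_T1", "t_stage", "T4", "T1"),
    "M1_vs_M0": GroupComparison("M1_vs_M0", "m_stage", "M1", "M0"),
    "N1_vs_N0": GroupComparison("N1_vs_N0", "n_stage", "N1", "N0"),
    "sex": GroupComparison("sex", "sex", "male", "female"),
}


@dataclass
class TestResult:
    """One Mann-Whitney comparison: metric x cohort x contrast."""

    metric: str
    cancer_type: str
    contrast: str
    n_a: int
    n_b: int
    u_statistic: float
    p_raw: float
    p_adjusted: float
    direction: int  # sign of (median_a - median_b)


@dataclass(frozen=True)
class SkipEntry:
    """A cohort excluded from a contrast, with the reason."""

    cancer_type: str
    contrast: str
    reason: str


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U (half-counting ties) and two-sided p-value.

    U counts pairs (i, j) with a_i > b_j plus half the tied pairs. The p-value
    is exact (full permutation null) when n_a + n_b <= 12 with no ties, and
    otherwise a tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        # all observations identical: no evidence either way
        logger.warning("all observations tied across both groups; p = 1")
        return float(a.size * b.size / 2.0), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(1.0, res.pvalue))


def bonferroni(p_values, family_size: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * family_size), elementwise.

    ``family_size`` may exceed the number of p-values supplied (tests belonging
    to the family may have been computed elsewhere or skipped).
    """
    p = np.asarray(p_values, float)
    if family_size < p.size:
        raise ValueError("family_size must be at least the number of p-values")
    if p.size and ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, p * family_size)


def _tumor_only(data: pd.DataFrame) -> pd.DataFrame:
    if "sample_class" not in data.columns:
        return data
    cls = data["sample_class"].map(lambda v: v.value if isinstance(v, TumorClass) else str(v))
    return data[cls == TumorClass.TUMOR.value]


def run_contrast(
    data: pd.DataFrame,
    comparison: GroupComparison,
    min_group_size: int = 3,
    metrics: Sequence[str] = METRIC_NAMES,
) -> tuple[list[TestResult], list[SkipEntry]]:
    """One Mann-Whitney test per metric per cohort for a clinical contrast.

    ``data`` holds one row per tumor sample with metric columns plus
    ``cancer_type``, the contrast's clinical column, and optionally
    ``sample_class`` (non-tumor rows are dropped). Cohorts where either group
    has fewer than ``min_group_size`` samples are skipped and listed. Adjusted
    p-values are Bonferroni within the family of cohorts tested for each
    (metric, contrast); the family size is the number of cohorts tested.
    """
    data = _tumor_only(data)
    col = comparison.column
    results: list[TestResult] = []
    skips: list[SkipEntry] = []
    per_cohort: list[tuple[str, pd.DataFrame, pd.DataFrame]] = []
    for cohort, sub in data.groupby("cancer_type", sort=True):
        ga = sub[sub[col] == comparison.group_a_label]
        gb = sub[sub[col] == comparison.group_b_label]
        if len(ga) < min_group_size or len(gb) < min_group_size:
            skips.append(
                SkipEntry(
                    str(cohort),
                    comparison.contrast,
                    f"group sizes {comparison.group_a_label}={len(ga)}, "
                    f"{comparison.group_b_label}={len(gb)} below minimum {min_group_size}",
                )
            )
            continue
        per_cohort.append((str(cohort), ga, gb))

    family_size = len(per_cohort)
    for cohort, ga, gb in per_cohort:
        for metric in metrics:
            va = ga[metric].to_numpy(float)
            vb = gb[metric].to_numpy(float)
            u, p = mann_whitney_u(va, vb)
            results.append(
                TestResult(
                    metric=metric,
                    cancer_type=cohort,
                    contrast=comparison.contrast,
                    n_a=len(va),
                    n_b=len(vb),
                    u_statistic=u,
                    p_raw=p,
                    p_adjusted=float(bonferroni([p], family_size)[0]),
                    direction=int(np.sign(np.median(va) - np.median(vb))),
                )
            )
    return results, skips


def run_sex_contrast(
    data: pd.DataFrame,
    excluded_cohorts: Iterable[str] = DEFAULT_SINGLE_SEX_COHORTS,
    min_group_size: int = 3,
    metrics: Sequence[str] = METRIC_NAMES,
) -> tuple[list[TestResult], list[SkipEntry]]:
    """Male-vs-female comparison after removing predominantly single-sex cohorts."""
    excluded = set(excluded_cohorts)
    kept = data[~data["cancer_type"].isin(excluded)]
    return run_contrast(kept, CONTRASTS["sex"], min_group_size=min_group_size, metrics=metrics)


def top_k(results: Iterable[TestResult], k: int = 10) -> list[TestResult]:
    """Per (metric, contrast), the k results with smallest adjusted p.

    Ties broken by smaller raw p, then cohort label lexicographically. Panels
    with fewer than k results return all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    frame: dict[tuple[str, str], list[TestResult]] = {}
    for r in results:
        frame.setdefault((r.metric, r.contrast), []).append(r)
    out: list[TestResult] = []
    for key in sorted(frame):
        ranked = sorted(frame[key], key=lambda r: (r.p_adjusted, r.p_raw, r.cancer_type))
        out.extend(ranked[:k])
    return out


def results_to_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    cols = ["metric", "cancer_type", "contrast", "n_a", "n_b", "u_statistic", "p_raw", "p_adjusted", "direction"]
    rows = [{c: getattr(r, c) for c in cols} for r in results]
    return pd.DataFrame(rows, columns=cols)


def skips_to_frame(skips: Iterable[SkipEntry]) -> pd.DataFrame:
    cols = ["cancer_type", "contrast", "reason"]
    rows = [{c: getattr(s, c) for c in cols} for s in skips]
    return pd.DataFrame(rows, columns=cols)
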