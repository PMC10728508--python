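"""Reading, validating, and annotating segmented copy-number and clinical tables.

Segmented copy-number data arrive as SEG-dialect tab-separated tables: one row
per (sample, chromosome, interval) with a per-segment mean log2 copy ratio.
This module parses and normalizes them into a :class:`SegmentTable`, classifies
samples as tumor vs. non-tumor from their sample-type label, and collapses AJCC
TNM stage strings (``"T1a"`` -> ``"T1"``) for downstream group comparisons.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized chromosome labels, in canonical order: autosomes 1-22, then X, Y.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

#: Sample-type labels classified as non-tumor (exact, case-sensitive match).
NON_TUMOR_LABELS: frozenset[str] = frozenset(
    {
        "Blood Derived Normal",
        "Solid Tissue Normal",
        "Bone Marrow Normal",
        "Buccal Cell Normal",
    }
)

#: Sample-type labels classified as tumor (exact, case-sensitive match).
TUMOR_LABELS: frozenset[str] = frozenset(
    {
        "Metastatic",
        "Primary Blood Derived Cancer",
        "Primary Tumor",
        "Recurrent Tumor",
        "Additional - New Primary",
        "Primary Blood Derived Cancer - Peripheral Blood",
    }
)


class TumorClass(str, Enum):
    TUMOR = "TUMOR"
    NON_TUMOR = "NON_TUMOR"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class SampleClass:
    """A sample-type label together with its tumor/non-tumor classification."""

    label: str
    cls: TumorClass


class SegFormatError(ValueError):
    """The file as a whole is malformed (missing column, duplicate key...)."""


class SegRecordError(ValueError):
    """One or more rows violate record invariants; carries 1-based line numbers."""

    def __init__(self, message: str, lines: list[int]):
        super().__init__(f"{message} (line(s): {', '.join(map(str, lines))})")
        self.lines = lines


@dataclass(frozen=True)
class SegDialect:
    """Column-name mapping for a SEG-style table."""

    sample: str = "Sample"
    chromosome: str = "Chromosome"
    start: str = "Start"
    end: str = "End"
    num_probes: str = "Num_Probes"
    segment_mean: str = "Segment_Mean"


@dataclass(frozen=True)
class Violation:
    """One structural problem found by :func:`validate_segments`."""

    sample_id: str
    chromosome: str
    kind: str  # "overlap" | "unsorted"
    start_bp: int
    end_bp: int
    detail: str


def normalize_chromosome(label: object) -> Optional[str]:
    """Map a raw chromosome label to the canonical set, or None if unrecognized.

    Accepts an optional ``chr`` prefix and integer-typed labels.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s in ("x", "y"):
        s = s.upper()
    if s.endswith(".0"):  # pandas float-read of an integer column
        s = s[:-2]
    return s if s in _CHROM_RANK else None


@dataclass
class SegmentTable:
    """Segmented copy-number records, grouped by sample and coordinate-sorted.

    Backed by a DataFrame with columns ``sample_id, chromosome, start_bp,
    end_bp, num_probes, segment_mean``; rows are sorted by
    (sample_id, chromosome rank, start_bp). Coordinates are 1-based inclusive
    by default (segment length = end - start + 1).
    """

    df: pd.DataFrame

    COLUMNS = ("sample_id", "chromosome", "start_bp", "end_bp", "num_probes", "segment_mean")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SegmentTable":
        """Build from a raw frame with the canonical columns, sorting as needed."""
        out = df.loc[:, list(cls.COLUMNS)].copy()
        out["sample_id"] = out["sample_id"].astype(str)
        out["chromosome"] = out["chromosome"].astype(str)
        out["start_bp"] = out["start_bp"].astype(np.int64)
        out["end_bp"] = out["end_bp"].astype(np.int64)
        out["num_probes"] = out["num_probes"].astype("Int64")
        out["segment_mean"] = out["segment_mean"].astype(float)
        rank = out["chromosome"].map(_CHROM_RANK)
        if rank.isna().any():
            bad = sorted(out.loc[rank.isna(), "chromosome"].unique())
            raise SegFormatError(f"unrecognized chromosome label(s): {bad}")
        out = (
            out.assign(_rank=rank)
            .sort_values(["sample_id", "_rank", "start_bp"], kind="mergesort")
            .drop(columns="_rank")
            .reset_index(drop=True)
        )
        return cls(out)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    @property
    def n_samples(self) -> int:
        return self.df["sample_id"].nunique()

    def per_sample(self) -> Iterator[tuple[str, pd.DataFrame]]:
        """Yield (sample_id, segment frame) pairs in sorted sample order."""
        for sid, sub in self.df.groupby("sample_id", sort=True):
            yield str(sid), sub

    def subset(self, sample_ids) -> "SegmentTable":
        keep = self.df["sample_id"].isin(set(sample_ids))
        return SegmentTable(self.df.loc[keep].reset_index(drop=True))

    def write(self, path, dialect: SegDialect = SegDialect()) -> None:
        """Write in the SEG dialect; the inverse of :func:`read_segments`."""
        out = self.df.rename(
            columns={
                "sample_id": dialect.sample,
                "chromosome": dialect.chromosome,
                "start_bp": dialect.start,
                "end_bp": dialect.end,
                "num_probes": dialect.num_probes,
                "segment_mean": dialect.segment_mean,
            }
        )
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_segments(path, dialect: SegDialect = SegDialect()) -> SegmentTable:
    """Read a SEG-dialect file into a sorted, grouped :class:`SegmentTable`.

    Rows on unrecognized contigs are dropped with a warning; rows violating
    record invariants (end < start, non-numeric or non-finite fields) raise
    :class:`SegRecordError` with their 1-based file line numbers.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = [dialect.sample, dialect.chromosome, dialect.start, dialect.end, dialect.segment_mean]
    for col in required:
        if col not in raw.columns:
            raise SegFormatError(f"missing required column: {col!r}")
    has_probes = dialect.num_probes in raw.columns

    # 1-based file line of each row: header is line 1.
    lines = raw.index.to_numpy() + 2

    start = pd.to_numeric(raw[dialect.start], errors="coerce")
    end = pd.to_numeric(raw[dialect.end], errors="coerce")
    mean = pd.to_numeric(raw[dialect.segment_mean], errors="coerce")
    bad_numeric = start.isna() | end.isna() | mean.isna() | ~np.isfinite(mean.fillna(np.inf))
    if bad_numeric.any():
        raise SegRecordError("unparseable or non-finite numeric field", list(lines[bad_numeric]))
    inverted = end.to_numpy() < start.to_numpy()
    if inverted.any():
        raise SegRecordError("end coordinate precedes start", list(lines[inverted]))

    chrom = raw[dialect.chromosome].map(normalize_chromosome)
    dropped = chrom.isna()
    if dropped.any():
        labels = sorted(raw.loc[dropped, dialect.chromosome].unique())
        logger.warning("dropping %d record(s) on unrecognized contig(s): %s", int(dropped.sum()), labels)

    probes = pd.to_numeric(raw[dialect.num_probes], errors="coerce") if has_probes else pd.Series(pd.NA, index=raw.index)
    frame = pd.DataFrame(
        {
            "sample_id": raw[dialect.sample],
            "chromosome": chrom,
            "start_bp": start,
            "end_bp": end,
            "num_probes": probes,
            "segment_mean": mean,
        }
    ).loc[~dropped]
    return SegmentTable.from_frame(frame)


def validate_segments(table: SegmentTable) -> list[Violation]:
    """Check per-(sample, chromosome) non-overlap and sort order.

    Returns a list of violations (empty iff the table satisfies its
    invariants); never raises.
    """
    violations: list[Violation] = []
    df = table.df
    if df.empty:
        return violations
    for (sid, chrom), sub in df.groupby(["sample_id", "chromosome"], sort=False):
        starts = sub["start_bp"].to_numpy()
        ends = sub["end_bp"].to_numpy()
        for i in range(1, len(sub)):
            if starts[i] < starts[i - 1]:
                violations.append(
                    Violation(str(sid), str(chrom), "unsorted", int(starts[i]), int(ends[i]),
                              f"start {starts[i]} before previous start {starts[i-1]}")
                )
            elif starts[i] <= ends[i - 1]:
                violations.append(
                    Violation(str(sid), str(chrom), "overlap", int(starts[i]), int(ends[i]),
                              f"overlaps previous segment ending at {ends[i-1]}")
                )
    return violations


def classify_sample(sample_type_label: str) -> SampleClass:
    """Classify a sample-type label as TUMOR, NON_TUMOR, or UNKNOWN.

    Matching is exact and case-sensitive against the standard label sets
    (4 non-tumor, 6 tumor); anything else is UNKNOWN.
    """
    if sample_type_label in NON_TUMOR_LABELS:
        cls = TumorClass.NON_TUMOR
    elif sample_type_label in TUMOR_LABELS:
        cls = TumorClass.TUMOR
    else:
        cls = TumorClass.UNKNOWN
    return SampleClass(label=sample_type_label, cls=cls)


_TNM_RE = re.compile(r"^([TNM])([0-9X])")


def collapse_tnm(raw_label: object) -> Optional[str]:
    """Collapse an AJCC stage label to its letter+digit prefix.

    ``"T1a"`` -> ``"T1"``; ``"N1b"`` -> ``"N1"``. Labels whose stage character
    is 'X' (``"MX"``), empty/missing values, and unparsable labels map to None
    (unparsable labels additionally log a warning). Idempotent.
    """
    if raw_label is None or (isinstance(raw_label, float) and np.isnan(raw_label)):
        return None
    s = str(raw_label).strip()
    if not s or s.lower() in ("nan", "na", "not reported", "[not available]"):
        return None
    m = _TNM_RE.match(s)
    if m is None:
        logger.warning("unparsable stage label: %r", s)
        return None
    letter, digit = m.group(1), m.group(2)
    if digit == "X":
        return None
    return letter + digit


#: Clinical-table column names (tab-separated dialect).
CLINICAL_COLUMNS = (
    "patient_id",
    "cancer_type",
    "sample_type",
    "ajcc_pathologic_t",
    "ajcc_pathologic_n",
    "ajcc_pathologic_m",
    "ajcc_clinical_m",
    "gender",
)


@dataclass
class ClinicalTable:
    """Per-patient clinical records with collapsed T/N/M stages and sex.

    Columns: ``patient_id, cancer_type, sample_type, t_raw, n_raw, m_raw,
    t_stage, n_stage, m_stage, sex``. One row per patient.
    """

    df: pd.DataFrame

    @classmethod
    def from_raw_frame(cls, raw: pd.DataFrame, m_attribute: str = "ajcc_pathologic_m") -> "ClinicalTable":
        if raw["patient_id"].duplicated().any():
            dups = sorted(raw.loc[raw["patient_id"].duplicated(), "patient_id"].unique())
            raise SegFormatError(f"duplicate patient_id(s): {dups}")
        if m_attribute not in raw.columns:
            raise SegFormatError(f"missing metastasis column: {m_attribute!r}")

        def _sex(v: object) -> Optional[str]:
            s = str(v).strip().lower()
            return s if s in ("female", "male") else None

        df = pd.DataFrame(
            {
                "patient_id": raw["patient_id"].astype(str),
                "cancer_type": raw["cancer_type"].astype(str),
                "sample_type": raw.get("sample_type", pd.Series("", index=raw.index)),
                "t_raw": raw.get("ajcc_pathologic_t"),
                "n_raw": raw.get("ajcc_pathologic_n"),
                "m_raw": raw[m_attribute],
            }
        )
        df["t_stage"] = df["t_raw"].map(collapse_tnm)
        df["n_stage"] = df["n_raw"].map(collapse_tnm)
        df["m_stage"] = df["m_raw"].map(collapse_tnm)
        df["sex"] = raw["gender"].map(_sex)
        return cls(df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    def write(self, path) -> None:
        out = pd.DataFrame(
            {
                "patient_id": self.df["patient_id"],
                "cancer_type": self.df["cancer_type"],
                "sample_type": self.df["sample_type"],
                "ajcc_pathologic_t": self.df["t_raw"],
                "ajcc_pathologic_n": self.df["n_raw"],
                "ajcc_pathologic_m": self.df["m_raw"],
                "ajcc_clinical_m": self.df["m_raw"],
                "gender": self.df["sex"],
            }
        )
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_clinical(path, m_attribute: str = "ajcc_pathologic_m") -> ClinicalTable:
    """Read a per-patient clinical table, collapsing TNM stages on the fly.

    ``m_attribute`` selects which metastasis column is used (the adrenocortical
    ACC cohort uses the clinical rather than the pathologic M attribute).
    Missing stage/sex cells become missing values, not errors; a duplicated
    patient_id is a format error.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("patient_id", "cancer_type", "gender"):
        if col not in raw.columns:
            raise SegFormatError(f"missing required column: {col!r}")
    return ClinicalTable.from_raw_frame(raw, m_attribute=m_attribute)


def patient_prefix(sample_id: str, prefix_len: int = 12) -> str:
    """Patient identifier embedded in a sample identifier (barcode prefix)."""
    return sample_id[:prefix_len]
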