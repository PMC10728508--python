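"""End-to-end orchestration: ingest or simulate -> metrics -> correlations ->
associations -> ranked outputs, with a deterministic file manifest.

Every output is a tab-separated UTF-8/LF text file; floats are rendered with
6 significant digits. The manifest records a SHA-256 hash per file, so a rerun
with the same configuration and seed is verifiably bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import associations as assoc
from . import cohort as cohort_mod
from . import metrics as metrics_mod
from . import seg_io
from . import simulate as sim

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full parameterization of a pipeline run."""

    mode: str = "simulate"  # "simulate" | "seg_files"
    out_dir: str = "results"
    seed: int = 0
    seg_path: Optional[str] = None
    clinical_path: Optional[str] = None
    samples_path: Optional[str] = None  # optional sample_id -> sample_type manifest
    m_attribute: str = "ajcc_pathologic_m"
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    metric: metrics_mod.MetricConfig = field(default_factory=metrics_mod.MetricConfig)
    contrasts: tuple[str, ...] = ("T4_vs_T1", "M1_vs_M0", "N1_vs_N0", "sex")
    min_group_size: int = 3
    excluded_sex_cohorts: tuple[str, ...] = tuple(sorted(assoc.DEFAULT_SINGLE_SEX_COHORTS))
    top_k: int = 10
    patient_prefix_len: int = 12
    skip_invalid: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("simulate", "seg_files"):
            raise ValueError(f"unknown mode: {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "sim" in raw and isinstance(raw["sim"], dict):
            s = dict(raw["sim"])
            if "genome" in s and isinstance(s["genome"], dict):
                s["genome"] = sim.GenomeModel(
                    tuple(map(str, s["genome"]["names"])), tuple(map(int, s["genome"]["lengths"]))
                )
            elif s.get("genome") == "toy":
                s["genome"] = sim.GenomeModel.toy()
            if "effects" in s and isinstance(s["effects"], dict):
                s["effects"] = {k: sim.Effect(**v) for k, v in s["effects"].items()}
            if "cancer_types" in s:
                s["cancer_types"] = tuple(s["cancer_types"])
            raw["sim"] = sim.SimulationConfig(**s)
        if "metric" in raw and isinstance(raw["metric"], dict):
            raw["metric"] = metrics_mod.MetricConfig(**raw["metric"])
        for key in ("contrasts", "excluded_sex_cohorts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_tables(objects: dict[str, pd.DataFrame], directory) -> dict[str, Path]:
    """Write named DataFrames as TSV (header, LF, UTF-8); returns name -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name, df in objects.items():
        path = directory / f"{name}.tsv"
        try:
            _write_tsv(df, path)
        except OSError as exc:
            raise PipelineError("write", f"cannot write {path}: {exc}") from exc
        out[name] = path
    return out


def _load_inputs(cfg: RunConfig):
    """Returns (SegmentTable, ClinicalTable, sample_type mapping sample_id->label)."""
    if cfg.mode == "simulate":
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        cohort = sim.simulate_cohort(sim_cfg)
        types = dict(zip(cohort.truth["sample_id"], cohort.truth["sample_type"]))
        return cohort.segments, cohort.clinical, types
    try:
        segments = seg_io.read_segments(cfg.seg_path)
    except (OSError, seg_io.SegFormatError, seg_io.SegRecordError) as exc:
        raise PipelineError("ingest", f"reading segments {cfg.seg_path!r}: {exc}") from exc
    try:
        clinical = seg_io.read_clinical(cfg.clinical_path, m_attribute=cfg.m_attribute)
    except (OSError, seg_io.SegFormatError) as exc:
        raise PipelineError("ingest", f"reading clinical {cfg.clinical_path!r}: {exc}") from exc
    if cfg.samples_path:
        try:
            manifest = pd.read_csv(cfg.samples_path, sep="\t", dtype=str)
        except OSError as exc:
            raise PipelineError("ingest", f"reading samples {cfg.samples_path!r}: {exc}") from exc
        types = dict(zip(manifest["sample_id"], manifest["sample_type"]))
    else:
        # fall back to the clinical table's per-patient sample_type via the prefix join
        per_patient = dict(zip(clinical.df["patient_id"], clinical.df["sample_type"]))
        types = {
            sid: per_patient.get(seg_io.patient_prefix(sid, cfg.patient_prefix_len), "")
            for sid in segments.sample_ids
        }
    return segments, clinical, types


def build_annotated_scores(
    segments: seg_io.SegmentTable,
    clinical: seg_io.ClinicalTable,
    sample_types: dict[str, str],
    metric_cfg: metrics_mod.MetricConfig,
    prefix_len: int = 12,
) -> pd.DataFrame:
    """Per-sample metric scores joined to clinical covariates and tumor class."""
    scores = metrics_mod.compute_all(segments, metric_cfg)
    scores["patient_id"] = scores["sample_id"].map(lambda s: seg_io.patient_prefix(s, prefix_len))
    scores["sample_class"] = scores["sample_id"].map(
        lambda s: seg_io.classify_sample(sample_types.get(s, "")).cls.value
    )
    clin = clinical.df[["patient_id", "cancer_type", "t_stage", "n_stage", "m_stage", "sex"]]
    return scores.merge(clin, on="patient_id", how="left")


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Execute the full pipeline; returns {filename: sha256} and writes manifest.json."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    segments, clinical, sample_types = _load_inputs(cfg)

    # validation
    violations = seg_io.validate_segments(segments)
    vio_df = pd.DataFrame(
        [dataclasses.asdict(v) for v in violations],
        columns=["sample_id", "chromosome", "kind", "start_bp", "end_bp", "detail"],
    )
    if violations:
        bad = sorted(vio_df["sample_id"].unique())
        if cfg.skip_invalid:
            logger.warning("dropping %d invalid sample(s): %s", len(bad), bad)
            segments = segments.subset(set(segments.sample_ids) - set(bad))
        else:
            write_tables({"validation_report": vio_df}, out_dir)
            raise PipelineError("validate", f"invalid segments in sample(s): {bad}")

    # metrics
    try:
        annotated = build_annotated_scores(
            segments, clinical, sample_types, cfg.metric, prefix_len=cfg.patient_prefix_len
        )
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise PipelineError("metrics", str(exc)) from exc
    for cohort_name, sub in annotated.groupby("cancer_type", dropna=False):
        logger.info("cohort %s: %d sample(s)", cohort_name, len(sub))

    # distribution summaries
    summary = cohort_mod.summarize_distributions(annotated)

    # correlations: pooled over all tumor samples, then per cohort
    corr_frames = []
    tumor = annotated[annotated["sample_class"] == seg_io.TumorClass.TUMOR.value]
    try:
        pooled = cohort_mod.metric_correlation_matrix(tumor)
        corr_frames.append(pooled.to_long("ALL"))
    except (cohort_mod.InsufficientDataError, cohort_mod.UndefinedCorrelationError) as exc:
        logger.warning("pooled correlation skipped: %s", exc)
    for name, mat in cohort_mod.per_cohort_correlations(annotated).items():
        corr_frames.append(mat.to_long(name))
    correlations = (
        pd.concat(corr_frames, ignore_index=True)
        if corr_frames
        else pd.DataFrame(columns=["cancer_type", "metric_a", "metric_b", "rho"])
    )

    # associations
    results: list[assoc.TestResult] = []
    skips: list[assoc.SkipEntry] = []
    for contrast in cfg.contrasts:
        if contrast == "sex":
            r, s = assoc.run_sex_contrast(
                annotated, excluded_cohorts=cfg.excluded_sex_cohorts, min_group_size=cfg.min_group_size
            )
        else:
            r, s = assoc.run_contrast(
                annotated, assoc.CONTRASTS[contrast], min_group_size=cfg.min_group_size
            )
        results.extend(r)
        skips.extend(s)
    ranked = assoc.top_k(results, k=cfg.top_k)

    scores_cols = ["sample_id", *metrics_mod.METRIC_NAMES]
    paths = write_tables(
        {
            "validation_report": vio_df,
            "cin_scores": annotated[scores_cols],
            "distribution_summary": summary,
            "correlations": correlations,
            "associations": assoc.results_to_frame(results),
            "association_skips": assoc.skips_to_frame(skips),
            "top_k": assoc.results_to_frame(ranked),
        },
        out_dir,
    )
    manifest = {p.name: _sha256(p) for p in paths.values()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
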