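"""Synthetic segmented copy-number cohorts with known generating truth.

Each simulated sample is a full tiling of a model genome: per chromosome, a
Poisson number of breakpoints is placed uniformly, and each resulting segment
is independently aberrant with probability ``p_alt``. Aberrant segment means
are ``sign * (alt_mean + alt_sd * z)`` with the magnitude truncated below at
``min_alt_amplitude`` so that truth-level and threshold-level aberration
coincide when the neutral noise is small; neutral means are
``neutral_sd * z``. Clinical covariates (T stage, N, M, sex) are assigned in
balanced halves, and group effects multiply ``p_alt`` (capped at 1) and/or
``alt_mean`` for samples carrying the "case" level — tumor, T4, M1, N1, male.

Three independent random streams (segment structure, aberration status,
segment values) are spawned per sample, so increasing ``p_alt`` under a common
seed can only add aberrant segments, never rearrange the segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import erf, sqrt
from typing import Optional

import numpy as np
import pandas as pd

from .seg_io import ClinicalTable, SegmentTable

#: Covariate keys recognized in SimulationConfig.effects.
EFFECT_KEYS = ("tumor", "t", "m", "n", "sex")


class SimulationConfigError(ValueError):
    """Invalid simulation parameterization."""


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome labels and lengths (bp) of the simulated genome."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) != len(self.lengths) or not self.names:
            raise SimulationConfigError("names and lengths must be non-empty and aligned")
        if any(L <= 0 for L in self.lengths):
            raise SimulationConfigError("chromosome lengths must be positive")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @classmethod
    def default(cls) -> "GenomeModel":
        """22 autosomes with round lengths summing to ~2.9 Gbp."""
        mb = [250, 245, 200, 190, 180, 170, 160, 145, 140, 135,
              135, 135, 115, 105, 100, 90, 80, 80, 60, 65, 45, 50]
        return cls(tuple(str(i) for i in range(1, 23)), tuple(L * 1_000_000 for L in mb))

    @classmethod
    def toy(cls) -> "GenomeModel":
        """Three-chromosome genome for fast tests (240 Mbp total)."""
        return cls(("1", "2", "3"), (100_000_000, 80_000_000, 60_000_000))


@dataclass(frozen=True)
class Effect:
    """Multiplicative shift applied to case-group samples."""

    p_alt: float = 1.0
    alt_mean: float = 1.0

    def __post_init__(self):
        if self.p_alt < 0 or self.alt_mean < 0:
            raise SimulationConfigError("effect multipliers must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic cohort.

    breakpoint_rate
        expected breakpoints per Mb per sample (Poisson); 0.05/Mb yields
        ~150 segments on the default ~3 Gbp genome, the order observed in
        SNP-array segmentations of bulk tumors.
    p_alt
        baseline probability that a segment is aberrant (non-tumor scale;
        the default tumor effect triples it for tumor samples).
    neutral_sd / alt_mean / alt_sd / min_alt_amplitude
        log2-ratio units; see module docstring.
    n_per_group
        samples per level of each binary covariate; a cohort holds
        2 * n_per_group tumor samples, balanced on every covariate.
    effects
        mapping covariate key ("tumor", "t", "m", "n", "sex") -> Effect,
        applied to tumor samples / T4 / M1 / N1 / male respectively.
    paired_normals
        if True, each patient additionally contributes a non-tumor sample
        generated at baseline parameters (no effects).
    """

    genome: GenomeModel = field(default_factory=GenomeModel.default)
    breakpoint_rate: float = 0.05
    p_alt: float = 0.1
    neutral_sd: float = 0.05
    alt_mean: float = 0.5
    alt_sd: float = 0.1
    min_alt_amplitude: float = 0.2
    n_per_group: int = 50
    cancer_types: tuple[str, ...] = ("SIM1",)
    effects: dict = field(default_factory=lambda: {"tumor": Effect(p_alt=3.0)})
    paired_normals: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.p_alt <= 1:
            raise SimulationConfigError("p_alt must lie in [0, 1]")
        if min(self.breakpoint_rate, self.neutral_sd, self.alt_sd, self.min_alt_amplitude) < 0:
            raise SimulationConfigError("rates and standard deviations must be non-negative")
        if self.n_per_group < 1:
            raise SimulationConfigError("n_per_group must be >= 1")
        if self.alt_sd == 0 and self.alt_mean < self.min_alt_amplitude:
            raise SimulationConfigError("alt_mean below min_alt_amplitude with alt_sd=0: truncation unsatisfiable")
        for key, eff in self.effects.items():
            if key not in EFFECT_KEYS:
                raise SimulationConfigError(f"unknown effect key {key!r}; expected one of {EFFECT_KEYS}")
            if not isinstance(eff, Effect):
                raise SimulationConfigError(f"effect for {key!r} must be an Effect")


@dataclass
class SimulatedCohort:
    """Segments + clinical + per-sample generating truth."""

    segments: SegmentTable
    clinical: ClinicalTable
    truth: pd.DataFrame  # sample_id, patient_id, cancer_type, sample_type, stages, sex, p_alt, alt_mean


def _effective_params(cfg: SimulationConfig, flags: dict[str, bool]) -> tuple[float, float]:
    """(p_alt, alt_mean) after applying the effects active under ``flags``."""
    p, mu = cfg.p_alt, cfg.alt_mean
    for key, on in flags.items():
        if on and key in cfg.effects:
            p *= cfg.effects[key].p_alt
            mu *= cfg.effects[key].alt_mean
    return min(1.0, p), mu


def simulate_sample(
    genome: GenomeModel,
    p_alt: float,
    alt_mean: float,
    rng: np.random.Generator,
    sample_id: str = "S1",
    breakpoint_rate: float = 0.05,
    neutral_sd: float = 0.05,
    alt_sd: float = 0.1,
    min_alt_amplitude: float = 0.2,
) -> pd.DataFrame:
    """Simulate one sample's segment table (canonical columns, full tiling).

    Deterministic given the generator state. Uses three spawned sub-streams
    (structure, status, values) so that aberration status under a common seed
    is coupled across ``p_alt`` values.
    """
    if not 0 <= p_alt <= 1:
        raise SimulationConfigError("p_alt must lie in [0, 1]")
    structure_rng, status_rng, value_rng = rng.spawn(3)
    chroms: list[np.ndarray] = []
    all_starts: list[np.ndarray] = []
    all_ends: list[np.ndarray] = []
    all_means: list[np.ndarray] = []
    for name, length in zip(genome.names, genome.lengths):
        k = int(structure_rng.poisson(breakpoint_rate * length / 1e6))
        if k > 0:
            # breakpoints are segment-end positions in [1, length-1]
            cuts = np.unique(structure_rng.integers(1, length, size=k))
        else:
            cuts = np.empty(0, dtype=np.int64)
        bounds = np.concatenate([[0], cuts, [length]]).astype(np.int64)
        starts = bounds[:-1] + 1
        ends = bounds[1:]
        n_seg = len(starts)

        aberrant = status_rng.random(n_seg) < p_alt
        means = neutral_sd * value_rng.standard_normal(n_seg)
        n_ab = int(aberrant.sum())
        if n_ab:
            mag = alt_mean + alt_sd * value_rng.standard_normal(n_ab)
            for _ in range(1000):
                low = mag < min_alt_amplitude
                if not low.any():
                    break
                mag[low] = alt_mean + alt_sd * value_rng.standard_normal(int(low.sum()))
            else:
                raise SimulationConfigError("could not satisfy amplitude truncation; check alt_mean/alt_sd")
            sign = value_rng.integers(0, 2, size=n_ab) * 2 - 1
            means[aberrant] = sign * mag
        chroms.append(np.repeat(name, n_seg))
        all_starts.append(starts)
        all_ends.append(ends)
        all_means.append(means)
    starts = np.concatenate(all_starts)
    ends = np.concatenate(all_ends)
    lengths_bp = ends - starts + 1
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chromosome": np.concatenate(chroms),
            "start_bp": starts,
            "end_bp": ends,
            "num_probes": np.maximum(1, (lengths_bp * 6e-4).astype(np.int64)),
            "segment_mean": np.concatenate(all_means),
        }
    )


def _balanced(levels: tuple[str, str], n: int, rng: np.random.Generator) -> np.ndarray:
    arr = np.array([levels[0]] * (n // 2) + [levels[1]] * (n - n // 2))
    rng.shuffle(arr)
    return arr


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Simulate a multi-cohort study: segments, clinical table, truth.

    Per cohort, 2 * n_per_group patients each contribute one tumor sample
    (plus one paired non-tumor sample if configured); T stage (T1/T4, with
    random sub-stage suffixes), N (N0/N1), M (M0/M1), and sex are balanced
    and mutually independent. Bit-reproducible for a fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    seg_frames: list[pd.DataFrame] = []
    clin_rows: list[dict] = []
    truth_rows: list[dict] = []
    for ct in cfg.cancer_types:
        n = 2 * cfg.n_per_group
        t_lab = _balanced(("T1", "T4"), n, rng)
        n_lab = _balanced(("N0", "N1"), n, rng)
        m_lab = _balanced(("M0", "M1"), n, rng)
        sex = _balanced(("female", "male"), n, rng)
        t_suffix = rng.choice(["", "a", "b"], size=n)
        for i in range(n):
            pid = f"{ct[:4].ljust(4, 'X')}-{i:07d}"  # 12 characters, a stable join prefix
            flags = {
                "tumor": True,
                "t": t_lab[i] == "T4",
                "m": m_lab[i] == "M1",
                "n": n_lab[i] == "N1",
                "sex": sex[i] == "male",
            }
            p_eff, mu_eff = _effective_params(cfg, flags)
            sid = pid + "-T01"
            seg_frames.append(
                simulate_sample(
                    cfg.genome, p_eff, mu_eff, rng, sample_id=sid,
                    breakpoint_rate=cfg.breakpoint_rate, neutral_sd=cfg.neutral_sd,
                    alt_sd=cfg.alt_sd, min_alt_amplitude=cfg.min_alt_amplitude,
                )
            )
            truth_rows.append(
                {
                    "sample_id": sid, "patient_id": pid, "cancer_type": ct,
                    "sample_type": "Primary Tumor", "t_stage": t_lab[i], "n_stage": n_lab[i],
                    "m_stage": m_lab[i], "sex": sex[i], "p_alt": p_eff, "alt_mean": mu_eff,
                }
            )
            if cfg.paired_normals:
                nid = pid + "-N01"
                seg_frames.append(
                    simulate_sample(
                        cfg.genome, cfg.p_alt, cfg.alt_mean, rng, sample_id=nid,
                        breakpoint_rate=cfg.breakpoint_rate, neutral_sd=cfg.neutral_sd,
                        alt_sd=cfg.alt_sd, min_alt_amplitude=cfg.min_alt_amplitude,
                    )
                )
                truth_rows.append(
                    {
                        "sample_id": nid, "patient_id": pid, "cancer_type": ct,
                        "sample_type": "Solid Tissue Normal", "t_stage": t_lab[i],
                        "n_stage": n_lab[i], "m_stage": m_lab[i], "sex": sex[i],
                        "p_alt": cfg.p_alt, "alt_mean": cfg.alt_mean,
                    }
                )
            clin_rows.append(
                {
                    "patient_id": pid, "cancer_type": ct, "sample_type": "Primary Tumor",
                    "ajcc_pathologic_t": t_lab[i] + t_suffix[i], "ajcc_pathologic_n": n_lab[i],
                    "ajcc_pathologic_m": m_lab[i], "ajcc_clinical_m": m_lab[i], "gender": sex[i],
                }
            )
    segments = SegmentTable.from_frame(pd.concat(seg_frames, ignore_index=True))
    clinical = ClinicalTable.from_raw_frame(pd.DataFrame(clin_rows))
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(segments=segments, clinical=clinical, truth=truth)


def _phi(z: float) -> float:
    return 0.5 * (1.0 + erf(z / sqrt(2.0)))


def expected_altered_fraction(
    cfg: SimulationConfig,
    flags: Optional[dict[str, bool]] = None,
    threshold: float = 0.2,
) -> float:
    """Closed-form expected fraction of bases called aberrant at ``threshold``.

    Segment lengths are independent of aberration status, so the expected
    length-weighted altered fraction (mean FGA) equals the per-segment
    probability of exceeding the threshold:

        p_eff * P(|aberrant mean| >= t) + (1 - p_eff) * P(|neutral mean| >= t)

    with the aberrant magnitude a normal truncated below at
    ``min_alt_amplitude`` and the neutral mean a centered normal.
    """
    flags = {"tumor": True} if flags is None else flags
    p_eff, mu_eff = _effective_params(cfg, flags)
    trunc = cfg.min_alt_amplitude
    if cfg.alt_sd == 0:
        p_ab = 1.0 if mu_eff >= threshold else 0.0
    else:
        lo = max(threshold, trunc)
        num = 1.0 - _phi((lo - mu_eff) / cfg.alt_sd)
        den = 1.0 - _phi((trunc - mu_eff) / cfg.alt_sd)
        p_ab = num / den if den > 0 else 0.0
    if cfg.neutral_sd == 0:
        p_neutral = 0.0 if threshold > 0 else 1.0
    else:
        p_neutral = 2.0 * (1.0 - _phi(threshold / cfg.neutral_sd))
    return p_eff * p_ab + (1.0 - p_eff) * p_neutral
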