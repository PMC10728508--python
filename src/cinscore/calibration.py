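"""Simulation studies calibrating the association machinery.

Three reusable study procedures: type-I error of the per-(metric, contrast)
Bonferroni family under a null, power to detect an injected aberration-
probability effect through the full simulate -> score -> test path, and
agreement of mean simulated FGA with its closed-form expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import associations as assoc
from . import metrics as metrics_mod
from . import simulate as sim
from .pipeline import build_annotated_scores


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def typei_family_error_rate(
    n_families: int = 1000,
    cohorts_per_family: int = 20,
    n_per_group: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null families with any Bonferroni-adjusted p below alpha.

    A family is one (metric, contrast) panel: ``cohorts_per_family`` cohorts,
    each contributing a Mann-Whitney test between two groups drawn from the
    same distribution. Bonferroni should keep the family-wise rate below alpha.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_families):
        p_raw = np.empty(cohorts_per_family)
        for c in range(cohorts_per_family):
            a = rng.standard_normal(n_per_group)
            b = rng.standard_normal(n_per_group)
            _, p_raw[c] = assoc.mann_whitney_u(a, b)
        if (assoc.bonferroni(p_raw, cohorts_per_family) < alpha).any():
            hits += 1
    return hits / n_families


def power_injected_effect(
    n_replicates: int = 200,
    effect: float = 3.0,
    baseline_p_alt: float = 0.1,
    n_per_group: int = 50,
    metric: str = "fga",
    contrast: str = "T4_vs_T1",
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Detection rate of a multiplicative p_alt effect, end to end.

    Each replicate simulates one toy-genome cohort whose T4 patients carry an
    ``effect``-fold aberration probability, scores it, joins clinical data,
    runs the contrast, and checks the chosen metric's Bonferroni-adjusted p.
    """
    seeds = _child_seeds(seed, n_replicates)
    metric_cfg = metrics_mod.MetricConfig()
    hits = 0
    for s in seeds:
        cfg = sim.SimulationConfig(
            genome=sim.GenomeModel.toy(),
            p_alt=baseline_p_alt,
            n_per_group=n_per_group,
            effects={"t": sim.Effect(p_alt=effect)},
            seed=int(s),
        )
        cohort = sim.simulate_cohort(cfg)
        types = dict(zip(cohort.truth["sample_id"], cohort.truth["sample_type"]))
        annotated = build_annotated_scores(cohort.segments, cohort.clinical, types, metric_cfg)
        results, _ = assoc.run_contrast(annotated, assoc.CONTRASTS[contrast])
        by_metric = {r.metric: r for r in results}
        if metric in by_metric and by_metric[metric].p_adjusted < alpha:
            hits += 1
    return hits / n_replicates


@dataclass(frozen=True)
class RecoveryResult:
    """Mean simulated FGA vs. its closed-form expectation for one setting."""

    p_alt: float
    neutral_sd: float
    alt_mean: float
    alt_sd: float
    mean_fga: float
    expected: float
    se: float

    @property
    def z(self) -> float:
        return (self.mean_fga - self.expected) / self.se if self.se > 0 else 0.0


DEFAULT_RECOVERY_SETTINGS = (
    (0.2, 0.05, 0.5, 0.1),
    (0.05, 0.02, 0.4, 0.05),
    (0.4, 0.08, 0.6, 0.15),
)


def fga_recovery(
    settings=DEFAULT_RECOVERY_SETTINGS,
    n_samples: int = 500,
    threshold: float = 0.2,
    seed: int = 0,
) -> list[RecoveryResult]:
    """Monte-Carlo mean FGA against the analytic expectation, per setting."""
    out: list[RecoveryResult] = []
    for i, (p_alt, neutral_sd, alt_mean, alt_sd) in enumerate(settings):
        cfg = sim.SimulationConfig(
            genome=sim.GenomeModel.toy(), p_alt=p_alt, neutral_sd=neutral_sd,
            alt_mean=alt_mean, alt_sd=alt_sd, effects={},
        )
        rng = np.random.default_rng(_child_seeds(seed, len(settings))[i])
        fgas = np.empty(n_samples)
        for k in range(n_samples):
            df = sim.simulate_sample(
                cfg.genome, cfg.p_alt, cfg.alt_mean, rng, sample_id=f"S{k}",
                breakpoint_rate=cfg.breakpoint_rate, neutral_sd=cfg.neutral_sd,
                alt_sd=cfg.alt_sd, min_alt_amplitude=cfg.min_alt_amplitude,
            )
            fgas[k] = metrics_mod.fga(df, metrics_mod.MetricConfig(aberration_threshold=threshold))
        expected = sim.expected_altered_fraction(cfg, flags={}, threshold=threshold)
        out.append(
            RecoveryResult(
                p_alt=p_alt, neutral_sd=neutral_sd, alt_mean=alt_mean, alt_sd=alt_sd,
                mean_fga=float(fgas.mean()), expected=float(expected),
                se=float(fgas.std(ddof=1) / np.sqrt(n_samples)),
            )
        )
    return out
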