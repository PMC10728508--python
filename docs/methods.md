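# Methods

## Input model

The unit of analysis is a segmented copy-number profile: per sample, an
ordered set of non-overlapping genomic intervals, each with a mean log2 copy
ratio ȳᵢ (0 = neutral diploid signal, positive = gain, negative = loss).
Chromosomes are the autosomes 1–22 plus X and Y; records on other contigs are
dropped with a warning. Coordinates are treated as 1-based inclusive, so the
segment length is dᵢ = endᵢ − startᵢ + 1. SEG files in the wild are ambiguous
on this point, which only matters for length-weighted quantities at the
single-base level; the convention is a `MetricConfig.length_convention`
option (`"half_open"` gives dᵢ = endᵢ − startᵢ).

Samples are classified tumor vs. non-tumor by exact, case-sensitive match of
their sample-type label against the standard four non-tumor and six tumor
labels used in large consortium archives; anything else is UNKNOWN and is
excluded from summaries. Samples join to patients by identifier prefix
(default: the first 12 characters, the patient portion of a standard
barcode; configurable). AJCC stage strings are collapsed to their
letter+digit prefix ("T1a" → "T1"); 'X' stages ("MX") and unparsable labels
become missing, so the group contrasts below compare pure T1/T4, M0/M1,
N0/N1 groups. Patients contribute one tumor sample each by default; the
simulator's paired-normal option exercises the multi-sample path.

## Metric definitions and conventions

A segment is *aberrant* iff |ȳᵢ| ≥ t, with t = 0.2 log2-ratio units by
default — the conventional cut for SNP-array segment means, roughly a
single-copy change in half the cells of a diploid bulk sample.

- **TAI** = Σ dᵢ·ȳᵢ / Σ dᵢ over the aberrant segments (signed). Whether the
  average runs over aberrant segments only or all segments varies across the
  literature; `tai_aberrant_only` (default true) exposes both. When no
  segment is aberrant the score is defined as 0 rather than undefined, so
  flat normal profiles remain finite and comparable.
- **Modified TAI** = Σ dᵢ·|ȳᵢ| / Σ dᵢ over *all* segments: removing the sign
  makes gains and losses additive instead of cancelling.
- **CNA** counts aberrant segments that are separated from their
  neighborhood: with adjacency threshold d (default 0.2), a segment counts
  iff it is aberrant and the previous segment on the same chromosome exists
  and differs by more than d (`cna_neighbor_rule="previous"`). The variant
  requiring separation from *every existing* neighbor (previous and next,
  chromosome ends unconstrained) is available as `"both"`. The two rules
  differ e.g. on a two-segment +0.5/−0.5 chromosome (1 vs. 2); the
  previous-neighbor rule is the default because it treats the CNA count as a
  count of aberrant transitions along the profile and matches the package's
  worked example.
- **Break Points** = 2 × (number of aberrant segments): each aberrant
  segment contributes its two flanking breaks. Always even by construction.
- **Base Segments** = Σ dᵢ over aberrant segments, in bp.
- **FGA** = Base Segments / Σ dᵢ over all segments, in [0, 1]. The
  denominator is the sample's *covered* length, not a fixed genome size, so
  samples with different coverage remain comparable.

Strand is meaningless for copy-number segments and is ignored. All six
metrics are computed in one vectorized pass (`compute_all`); the test suite
checks it against a deliberately naive per-segment loop to 1e-12 on
simulated samples.

## Cohort comparison

Cross-metric agreement uses Spearman's rank correlation (Pearson correlation
of mid-ranks, the standard tie convention), pooled across all tumor samples
and within each cohort; cohorts with fewer than 3 tumor samples or a
constant metric are skipped with a warning. No p-values are attached to
correlations — the object of interest is the pattern of coefficients.
Distribution summaries report n, median, and quartiles (linear
interpolation) per cohort × metric × tumor class. For heatmap export,
`cluster_order` returns the leaf order of complete-linkage agglomerative
clustering on Euclidean distances; scipy's implementation resolves ties
deterministically by lower index, so identical inputs give identical orders.
Rendering itself is out of scope.

One note on naming: the six metrics are grouped as overall (TAI, Modified
TAI), event-count/structural (Break Points, CNA), and extent-of-alteration
(Base Segments, FGA) scores; usage of "numerical" vs. "structural" for the
latter two groups is inconsistent in the literature, so the grouping is
carried as data labels, never as logic.

## Association testing

Each metric is compared between two clinical groups per cohort with the
two-sided Mann-Whitney test, U counting pairs with aᵢ > bⱼ plus half the
tied pairs. The p-value is exact (full permutation null) when
n_a + n_b ≤ 12 with no ties — where enumeration is trivial — and otherwise
uses the tie-corrected normal approximation with continuity correction. The
degenerate all-tied case returns p = 1 with a warning. Contrasts are
T4 vs T1, M1 vs M0, N1 vs N0, and male vs female; the sex comparison
excludes cohorts occurring predominantly in one sex (default CESC, OV,
PRAD, TGCT, UCEC, UCS). Cohorts where either group has fewer than
`min_group_size` samples (default 3) are skipped and listed.

Bonferroni correction multiplies each raw p by its family size, capped at 1.
The family is pinned to per-(metric, contrast) across cohorts — the family
size is the number of cohorts actually tested for that panel — matching the
"top-k cohorts per metric and contrast" presentation of the ranked output;
`top_k` breaks ties by raw p, then cohort label. Each result carries a
direction (sign of the median difference, advanced-stage or male group
first) because significance alone does not say which group is more
unstable.

## Synthetic cohorts

The generator emulates the statistical shape of SNP-array segmentations
without modeling the platform. Per chromosome, the breakpoint count is
Poisson with mean λ·(length/1 Mb) and positions are uniform, so segments
tile each chromosome exactly; λ defaults to 0.05/Mb (~150 segments on the
~2.9 Gbp 22-autosome default genome, the order seen in bulk tumor
segmentations; a 240 Mbp 3-chromosome toy genome keeps tests fast). Each
segment is independently aberrant with probability `p_alt` (default 0.1);
aberrant means are ±(μ_a + σ_a·z) with random sign and magnitude truncated
below at `min_alt_amplitude` (default equal to t), neutral means are
σ_n·z. The truncation makes "aberrant in truth" and "aberrant by threshold"
coincide when σ_n is small, which is what makes power results interpretable.
Clinical covariates (T1/T4 with random sub-stage suffixes, N0/N1, M0/M1,
sex) are assigned in balanced halves, independently; group effects multiply
`p_alt` (capped at 1) and/or μ_a for the case level (tumor, T4, M1, N1,
male). The default configuration applies a 3× tumor burden effect only,
i.e. all stage and sex contrasts are null unless an effect is injected.

Because segment lengths are independent of aberration status, the expected
length-weighted altered fraction (mean FGA) has the closed form
p_eff·P(|aberrant mean| ≥ t) + (1 − p_eff)·P(|neutral mean| ≥ t), with
truncated-normal and normal tails respectively
(`expected_altered_fraction`); the test suite checks Monte-Carlo agreement
within 3 standard errors. Randomness is split into three spawned streams per
sample (structure, aberration status, values), so raising `p_alt` under a
common seed can only add aberrant segments — a monotonicity the tests
assert. The generator does not model whole-genome doubling, focal-vs-arm
structure, clonal mixtures, probe-level noise, or correlated covariates;
passing tests therefore demonstrate correctness of the scoring and testing
machinery under exchangeable segmentations, not robustness to those
real-data features.

## Calibration studies and problem sizes

`cinscore.calibration` packages three studies, used by the test suite and
the acceptance script:

- **Type-I error**: 1000 null families of 20 cohorts (two groups of 30 drawn
  from one distribution per cohort); the fraction of families with any
  Bonferroni-adjusted p < 0.05 is required to stay ≤ 0.07 (nominal 5% plus
  Monte-Carlo slack; Bonferroni is conservative). The study runs at the
  statistics level — drawing metric values directly — since segment-level
  detail is irrelevant to null calibration.
- **Power**: 200 replicates of one toy-genome cohort, 50 patients per
  T group, with a 3× `p_alt` effect on T4 over a 0.1 baseline, run through
  the full simulate → score → join → test path; the FGA panel must flag the
  effect at adjusted p < 0.05 in ≥ 90% of replicates (observed: essentially
  always).
- **Analytic recovery**: mean FGA over 500 samples vs. the closed form, for
  three parameter settings spanning low to high burden.

These sizes keep the default suite and the acceptance script each well
under a minute of compute for the stochastic parts while leaving the checks
statistically meaningful.

## Pipeline determinism and numerical notes

All outputs are tab-separated UTF-8/LF text with floats at 6 significant
digits; the run manifest records a SHA-256 hash per file, and a rerun with
the same configuration and seed is bit-identical (asserted in tests). Stage
failures abort with a stage-named error and nonzero exit; in
`skip_invalid` mode, samples failing segment validation are dropped and
reported without affecting other samples. Aberration uses ≥ t and adjacency
uses > d (boundary values count as aberrant but not as separated); empty
segment lists are errors rather than zero scores, while an empty *aberrant
set* yields the defined zeros.

## Known limitations

Metric values depend on the upstream segmentation; no ploidy or purity
correction, allele-specific calls, recurrence (GISTIC-style) analysis, or
per-gene annotation is attempted. Associations are single-factor two-group
comparisons — no multivariable modeling, survival analysis, or effect sizes
beyond direction. The sample-to-patient join is a bare prefix rule with no
barcode semantics.
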