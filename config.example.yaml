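# Example run configuration for `cinscore run-all --config config.example.yaml --out results`
# Flags on the command line override values given here.

mode: simulate          # "simulate" or "seg_files"
seed: 0
top_k: 10
min_group_size: 3
patient_prefix_len: 12  # sample -> patient join: first N characters of the sample id
skip_invalid: false     # drop samples failing validation instead of aborting

# seg_files mode inputs (ignored in simulate mode):
# seg_path: data/segments.seg
# clinical_path: data/clinical.tsv
# samples_path: data/samples.tsv   # optional sample_id -> sample_type manifest
# m_attribute: ajcc_pathologic_m   # use ajcc_clinical_m for the ACC cohort

sim:
  genome: toy           # "toy" (3 chromosomes, fast) or omit for the 22-autosome default
  breakpoint_rate: 0.05 # expected breakpoints per Mb per sample
  p_alt: 0.1            # baseline probability a segment is aberrant
  neutral_sd: 0.05      # log2-ratio noise of neutral segments
  alt_mean: 0.5         # mean |log2 ratio| of aberrant segments
  alt_sd: 0.1
  min_alt_amplitude: 0.2
  n_per_group: 25       # samples per level of each binary covariate (cohort size = 2x)
  cancer_types: [SIMA, SIMB]
  paired_normals: false
  effects:              # multiplicative shifts for tumor / T4 / M1 / N1 / male samples
    tumor: {p_alt: 3.0}
    # t: {p_alt: 2.0, alt_mean: 1.0}

metric:
  aberration_threshold: 0.2   # t: |segment mean| >= t marks a segment aberrant
  adjacency_difference: 0.2   # d: neighbor separation required by the CNA metric
  tai_aberrant_only: true
  length_convention: inclusive  # segment length = end - start + 1
  cna_neighbor_rule: previous   # or "both"

contrasts: [T4_vs_T1, M1_vs_M0, N1_vs_N0, sex]
excluded_sex_cohorts: [CESC, OV, PRAD, TGCT, UCEC, UCS]
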