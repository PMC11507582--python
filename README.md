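# panelscreen

Targeted-panel variant filtering, mutational-profile contrasts and
survival/response biomarker screening for ovarian tumor cohorts of four
aggressiveness classes (`BOT`, `BOT.V600E`, `lgOvCa`, `hgOvCa`).

The package provides, as composable modules and a CLI:

- **`panelscreen.cohort`** — a seeded synthetic cohort generator that
  emits a clinical table, per-sample VCFs, a transcript-level annotation
  table and per-region depth summaries, with planted per-gene per-group
  alteration frequencies, proportional-hazards survival effects,
  logistic response effects, and decoy calls that each violate exactly
  one filter gate.
- **`panelscreen.qc`** — pre-annotation filters: per-sample low-coverage
  region exclusion (mean depth < 5), allele-fraction filter (VAF < 0.10
  removed, computed from AD), quality gates (alt bases ≥ 2, QUAL ≥ 20,
  MQ ≥ 20, DP ≥ 5) and the SNP/non-SNP partition.
- **`panelscreen.annotate`** — transcript-row consolidation, impact
  stratification (HIGH / MODERATE / HIGH-or-MODERATE; LOW and MODIFIER
  never pass) and the retention rules: adverse clinical significance,
  SIFT/PolyPhen damage, novelty, fully-empty prediction fields, or
  population allele frequency < 0.01.
- **`panelscreen.profiles`** — samples × genes 0/1 alteration matrices
  (MISSING where coverage masking removed every region of a gene),
  per-group cumulative frequencies, Kruskal–Wallis + pairwise rank
  tests on per-sample variant counts, and pairwise per-gene 2×2
  contrasts (Fisher's exact when any expected cell < 5, else
  chi-squared) rolled up into a long-form comparison report.
- **`panelscreen.screen`** — per gene × endpoint × subgroup pairs of
  univariable and multivariable models (Cox for OS/DFS/RFS, logistic for
  CR/PS/microinvasion-implants), bootstrap cross-validated AUCs
  (out-of-bag evaluation), time-dependent ROC with Youden cutoffs,
  Kaplan–Meier risk stratification with the log-rank test, and the
  model-matching decision (both p < 0.05, concordant effect direction,
  all AUCs > 0.65).
- **`panelscreen.panels`** — the shipped 44-gene hereditary and 37-gene
  hot-spot enrichment panels (76 distinct genes in union).

## CLI

```sh
# generate a synthetic cohort bundle
panelscreen simulate --config examples/cohort.yaml --seed 7 --out out/bundle

# filter cascade + matrices + group-contrast report
panelscreen filter --bundle out/bundle --out out/reports

# full regression screen with bootstrap AUC matching
panelscreen screen --bundle out/bundle --out out/reports --seed 7 --boot 200

# everything in one deterministic run
panelscreen run-all --config examples/cohort.yaml --seed 7 --out out

# shipped panel bookkeeping
panelscreen panels
```

Every filter threshold is a flag with the published default
(`--min-vaf 0.10`, `--min-alt-bases 2`, `--min-qual 20`,
`--min-mapq 20`, `--min-depth 5`, `--min-region-depth 5`). A single
`--seed` fixes every output byte; rerunning any command with the same
inputs and seed produces checksum-identical files.

The cohort YAML accepts `group_sizes`, `gene_freqs`
(gene/group/stratum/prob entries), `survival_effects`
(gene/endpoint/log_hr), `response_effects` (gene/outcome/log_or),
`noise_vaf_rate`, `lowcov_region_rate` and `censoring_rate`; see
`examples/cohort.yaml`.

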