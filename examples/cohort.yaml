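# Example synthetic cohort configuration.
# Group sizes default to the study-like 53/23/10/139 when omitted.
panel: hereditary-44
group_sizes:
  BOT: 53
  BOT.V600E: 23
  lgOvCa: 10
  hgOvCa: 139
gene_freqs:
  - {gene: TP53,  group: hgOvCa,    stratum: HIGH,             prob: 0.70}
  - {gene: BRCA1, group: hgOvCa,    stratum: HIGH_OR_MODERATE, prob: 0.50}
  - {gene: BRCA2, group: hgOvCa,    stratum: HIGH_OR_MODERATE, prob: 0.40}
  - {gene: PARP1, group: BOT,       stratum: HIGH_OR_MODERATE, prob: 0.35}
  - {gene: PARP1, group: BOT.V600E, stratum: HIGH_OR_MODERATE, prob: 0.35}
  - {gene: FANCA, group: BOT,       stratum: MODERATE,         prob: 0.30}
survival_effects:
  - {gene: PARP1, endpoint: RFS, log_hr: 1.92}   # HR ~ 6.8
  - {gene: BRCA2, endpoint: OS,  log_hr: -0.69}  # HR ~ 0.5
response_effects:
  - {gene: BRCA2, outcome: CR, log_or: 1.95}     # OR ~ 7
noise_vaf_rate: 1.0
other_decoy_rate: 0.3
lowcov_region_rate: 0.02
censoring_rate: 0.2
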