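# Crossover assessment fixture: 7 embryos with paralog-templated HDR at the
# target locus. The paralog locus amplifies in 5 (all intact -> non-crossover)
# and fails to amplify in 2 (indeterminate). Includes the matching
# target-locus mixtures so the cohort can also be classified end to end.
name: crossover_cohort
locus:
  length: 400
  n_discriminating: 4
  seed: 31
donor:
  n_signatures: 6
  arm_length: 63
  seed: 32
embryos:
  - {count: 7, prefix: rec, n_reads: 50, mixture: {WT: 20, NHEJ_INDEL: 15, HDR_PARALOG: 15}}
paralog_embryos:
  - {count: 5, prefix: rec, amplified: true, crossover: false, n_reads: 10}
  - {count: 2, prefix: drop, amplified: false, crossover: false, n_reads: 0}
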