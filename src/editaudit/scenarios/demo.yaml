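# Small end-to-end demo: a mixed cohort plus an exome plant specification
# exercising every stage of the off-target filter chain.
name: demo
locus:
  length: 400
  n_discriminating: 4
  seed: 41
donor:
  n_signatures: 6
  arm_length: 63
  seed: 42
embryos:
  - {count: 2, prefix: intact, n_reads: 20, mixture: {WT: 20}}
  - {count: 3, prefix: nhej, n_reads: 20, mixture: {WT: 10, NHEJ_INDEL: 10}}
  - {count: 1, prefix: oligo, n_reads: 20, mixture: {WT: 8, NHEJ_INDEL: 8, HDR_OLIGO: 4}}
  - {count: 2, prefix: rec, n_reads: 20, mixture: {WT: 8, NHEJ_INDEL: 6, HDR_PARALOG: 6}}
  - {count: 1, prefix: mosaic, n_reads: 20, mixture: {WT: 5, NHEJ_INDEL: 8, HDR_PARTIAL: 7}}
  - {count: 1, prefix: dropout, n_reads: 0, amplified: false, mixture: {WT: 1}}
paralog_embryos:
  - {count: 2, prefix: rec, amplified: true, crossover: false, n_reads: 10}
exome_plant:
  on_target: 1
  off_target: 2
  nuisance_exon: 3
  nuisance_support: 3
  nuisance_low_complexity: 3
  nuisance_homopolymer: 3
  background: 3
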