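# Injected-embryo cohort: four injection groups collapsed to their outcome
# classes. 59 GFP+ embryos; 5 fail whole-genome amplification; of the 54
# amplified, 28 show Cas9 cleavage (17 NHEJ-only, 4 with oligo-HDR reads,
# 7 with paralog-HDR conversion tracts). Mixture values are clone counts.
name: embryo_cohort
locus:
  length: 400
  n_discriminating: 4
  seed: 11
donor:
  n_signatures: 6
  arm_length: 63
  seed: 12
embryos:
  - {count: 26, prefix: intact, n_reads: 50, mixture: {WT: 50}}
  - {count: 17, prefix: nhej, n_reads: 50, mixture: {WT: 25, NHEJ_INDEL: 25}}
  - {count: 4, prefix: oligo, n_reads: 50, mixture: {WT: 20, NHEJ_INDEL: 20, HDR_OLIGO: 10}}
  - {count: 7, prefix: paralog, n_reads: 50, mixture: {WT: 20, NHEJ_INDEL: 15, HDR_PARALOG: 15}}
  - {count: 5, prefix: dropout, n_reads: 0, amplified: false, mixture: {WT: 1}}
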