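# 293T co-transfection clone fixture: one cell pool, 29 subcloned amplicon
# sequences of which 14 carry all six donor signatures (oligo HDR), 10 carry
# NHEJ indels and 5 are wild type.
name: clones_293t
locus:
  length: 400
  n_discriminating: 4
  seed: 21
donor:
  n_signatures: 6
  arm_length: 63
  seed: 22
embryos:
  - {count: 1, prefix: pool, n_reads: 29, mixture: {HDR_OLIGO: 14, NHEJ_INDEL: 10, WT: 5}}
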