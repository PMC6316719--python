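# Default annotation profile: the criteria used for the SPP1 genome
# re-annotation (small circular Bacillus phage, heavy-strand coding).
topology: circular
orf:
  min_aa: 45
  start_codons: [ATG, GTG, TTG]
  strand_mode: heavy_only
  coupling_max_gap: 1
rbs:
  antisd: UCUUUCCUCCACUAG
  anchor_index: 8
  spacing_min: 8
  spacing_max: 14
  min_paired: 4
  max_mismatch: 2
  window: 25
  dual_start_codons: 15
terminators:
  window: 60
  min_stem: 4
  max_stem: 15
  loop_min: 3
  loop_max: 12
  max_stem_mismatch: 1
  min_u: 3
  u_window: 8
composition:
  at_island_window: 50
  at_island_threshold: 0.75
motifs:
  min_ext: 10
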