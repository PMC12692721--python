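# Catalog of the top-ranked RMSD-based descriptors (structural-alphabet
# t-statistic and PB-sequence-probability recipes). `rank` is the influence
# order from the published greedy selection; lower rank = larger contribution.
# A single-letter `pb` denotes a per-block t-statistic descriptor; a longer
# string denotes a PB-sequence probability descriptor (see descriptors_rmsd
# module docs for this interpretation choice).
descriptors:
  - {rank: 1,  alphabet: Full5,         kind: pb_seq_prob, pb: acdddfb, offset: 0,  power: 1}
  - {rank: 2,  alphabet: Full5,         kind: pb_seq_prob, pb: pap,     offset: 0,  power: 1}
  - {rank: 3,  alphabet: Full5,         kind: pb_seq_prob, pb: ehjia,   offset: 0,  power: 1}
  - {rank: 4,  alphabet: Full5,         kind: pb_seq_prob, pb: mmmmm,   offset: 5,  power: 1}
  - {rank: 7,  alphabet: PB_W7_tail_GP, kind: pb_seq_prob, pb: mmmmmmm, offset: 0,  power: 1}
  - {rank: 11, alphabet: Full5,         kind: pb_seq_prob, pb: mmmmm,   offset: -4, power: 1}
  - {rank: 14, alphabet: Full5,         kind: pb_seq_prob, pb: pafkl,   offset: 0,  power: 1}
  - {rank: 16, alphabet: Full5,         kind: pb_seq_prob, pb: ddddd,   offset: 0,  power: 1}
  - {rank: 17, alphabet: Full5,         kind: pb_seq_prob, pb: klmmm,   offset: 2,  power: 1}
  - {rank: 22, alphabet: PB_w11_tail,   kind: pb_seq_prob, pb: pgb,     offset: 0,  power: 2}
  - {rank: 24, alphabet: PB_w11_tail,   kind: pb_seq_prob, pb: jia,     offset: 0,  power: 1}
  - {rank: 30, alphabet: PB_W3,         kind: pb_seq_prob, pb: acdddfb, offset: 0,  power: 1}
  - {rank: 31, alphabet: Full5,         kind: pb_seq_prob, pb: ddfbg,   offset: 0,  power: 1}
  - {rank: 34, alphabet: Full5,         kind: pb_seq_prob, pb: ghi,     offset: 0,  power: 1}
  - {rank: 36, alphabet: Full5,         kind: pb_seq_prob, pb: kln,     offset: -3, power: 2}
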