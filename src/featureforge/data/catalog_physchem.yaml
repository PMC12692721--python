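# Catalog of physicochemical descriptors: periodic recipes (property scale,
# period T in residues, number of periods n_T, decay strength A, power) and
# non-periodic window recipes (property scale, window offsets relative to the
# target residue, decay strength A, power). `rank` is the influence order
# from the published greedy selection. The accession names refer to AAindex
# scales; this repo ships synthetic stand-in values for them (see data/
# synthetic_property_scales.txt) plus the real Kyte-Doolittle scale.
periodic:
  - {rank: 25, accession: KARS160108, T: 3.7,  n_T: 5, A: 1.0, power: 1}
  - {rank: 51, accession: MUNV940103, T: 10.0, n_T: 3, A: 1.0, power: 2}
  - {rank: 63, accession: MIYS990102, T: 3.6,  n_T: 7, A: 1.0, power: 1}
  - {rank: 77, accession: MUNV940102, T: 3.0,  n_T: 2, A: 1.0, power: 1}
window:
  - {rank: 6,  accession: MUNV940103, left: -5,  right: 6,  A: 0.0, power: 1}
  - {rank: 8,  accession: PTIO830101, left: -5,  right: 6,  A: 0.0, power: 1}
  - {rank: 21, accession: MUNV940102, left: -5,  right: 16, A: 0.0, power: 3}
  - {rank: 35, accession: PTIO830101, left: -15, right: 16, A: 0.0, power: 3}
  - {rank: 60, accession: PONP800104, left: -5,  right: 5,  A: 0.0, power: 2}
  - {rank: 87, accession: PTIO830101, left: -5,  right: 5,  A: 0.0, power: 3}
  - {rank: 93, accession: MUNV940103, left: -5,  right: 5,  A: 0.0, power: 2}
special:
  - {rank: 12, kind: disorder, mode: short, power: 3}
  - {rank: 73, kind: end_n, within: 3, power: 3}
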