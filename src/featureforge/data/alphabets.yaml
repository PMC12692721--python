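# Reduced-alphabet definitions.
#
# Each alphabet partitions the 20 canonical one-letter codes into equivalence
# groups, per fragment position. `all_positions` is shorthand for the same
# partition at every position; `positions` gives one partition per position.
# Groups are strings of letters. A letter may appear in exactly one group per
# position. `wildcard: true` routes letters outside the partition (e.g. 'X')
# into a catch-all class instead of raising.
#
# The named `PB_*` alphabets reserve catalog names whose exact published
# group membership is not distributed here; their definitions below are
# placeholder groupings and are flagged `unverified`.
alphabets:
  - name: Full3
    fragment_length: 3
    full: true
    wildcard: true
  - name: Full5
    fragment_length: 5
    full: true
    wildcard: true
  - name: Full7
    fragment_length: 7
    full: true
    wildcard: true
  - name: Full11
    fragment_length: 11
    full: true
    wildcard: true
  - name: Aliphatic5
    fragment_length: 5
    all_positions: ["GAVLI", "CM", "YWF", "DE", "KR", "H", "NQ", "ST", "P"]
    wildcard: true
  - name: PB_W3
    fragment_length: 3
    unverified: true
    all_positions: ["GAVLI", "CM", "YWF", "DE", "KRH", "NQ", "ST", "P"]
    wildcard: true
  - name: PB_W7_tail_GP
    fragment_length: 7
    unverified: true
    positions:
      - ["G", "P", "ACDEFHIKLMNQRSTVWY"]
      - ["G", "P", "ACDEFHIKLMNQRSTVWY"]
      - full
      - full
      - full
      - ["G", "P", "ACDEFHIKLMNQRSTVWY"]
      - ["G", "P", "ACDEFHIKLMNQRSTVWY"]
    wildcard: true
  - name: PB_w11_tail
    fragment_length: 11
    unverified: true
    positions:
      - ["GAVLI", "CM", "YWF", "DEKRH", "NQSTP"]
      - ["GAVLI", "CM", "YWF", "DEKRH", "NQSTP"]
      - ["GAVLI", "CM", "YWF", "DEKRH", "NQSTP"]
      - full
      - full
      - full
      - full
      - full
      - ["GAVLI", "CM", "YWF", "DEKRH", "NQSTP"]
      - ["GAVLI", "CM", "YWF", "DEKRH", "NQSTP"]
      - ["GAVLI", "CM", "YWF", "DEKRH", "NQSTP"]
    wildcard: true
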