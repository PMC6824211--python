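classes: [NoColor, Eye1, Eye2, Holstein, Watson, FullCoat]
masking_classes: [Eye1]
loci:
  C:
    chromosome: Vu07
    alleles: [C0, C1, C2]
    dominance:
      - [C2, C0]
      - [C2, C1]
    unresolved_pairs:
      - [C1, C0]
  W:
    chromosome: Vu09
    alleles: [W0, W1]
    dominance:
      - [W1, W0]
    unresolved_pairs: []
  H:
    chromosome: Vu10
    alleles: [H0, H1]
    dominance:
      - [H1, H0]
    unresolved_pairs: []
rules:
  - when: {C: [C0]}
    pattern: NoColor
  - when: {C: [C1]}
    pattern: Eye1
  - when: {C: [C2], H: [H0], W: [W0]}
    pattern: Eye2
  - when: {C: [C2], H: [H1], W: [W0]}
    pattern: Holstein
  - when: {C: [C2], H: [H0], W: [W1]}
    pattern: Watson
  - when: {C: [C2], H: [H1], W: [W1]}
    pattern: FullCoat
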