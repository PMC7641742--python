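name: PIM1-SLQS02 Form 2
sequence: GGGAGGGCGCGCCAGCGGGGTCGGGC
syn:
- 2
- 6
- 18
- 24
tetrads:
- members:
  - 2
  - 7
  - 18
  - 25
  kind: G-tetrad
  hbond_direction: unspecified
  slipped: false
- members:
  - 3
  - 24
  - 19
  - 6
  kind: G-tetrad
  hbond_direction: unspecified
  slipped: false
- members:
  - 1
  - 26
  - 17
  - 8
  kind: GCGC-tetrad
  hbond_direction: unspecified
  slipped: true
pairs:
- g: 1
  c: 26
  role: junction
- g: 17
  c: 8
  role: junction
- g: 9
  c: 16
  role: stem
- g: 15
  c: 10
  role: stem
loops:
- kind: lateral
  start: 4
  end: 5
- kind: stem-loop
  start: 11
  end: 14
- kind: lateral
  start: 20
  end: 23
grooves:
- wide
- narrow
- wide
- narrow
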