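name: PIM1-SLQS07 Form 1
sequence: GCGGGAGGGCGCGCCAGCGGGGTCGGG
syn:
- 1
- 3
- 7
- 20
- 21
- 25
tetrads:
- members:
  - 3
  - 25
  - 22
  - 7
  kind: G-tetrad
  hbond_direction: anticlockwise
  slipped: false
- members:
  - 4
  - 8
  - 21
  - 26
  kind: G-tetrad
  hbond_direction: clockwise
  slipped: false
- members:
  - 5
  - 9
  - 20
  - 27
  kind: G-tetrad
  hbond_direction: clockwise
  slipped: false
pairs:
- g: 19
  c: 10
  role: junction
- g: 11
  c: 18
  role: stem
- g: 17
  c: 12
  role: stem
loops:
- kind: propeller
  start: 6
  end: 6
- kind: lateral
  start: 23
  end: 24
- kind: stem-loop
  start: 13
  end: 16
grooves:
- wide
- medium
- medium
- narrow
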