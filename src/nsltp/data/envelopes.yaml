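# Admissible inter-cysteine spacing sets per nsLTP type, deduced from the 63
# mature B. rapa sequences (one row per type; s1..s5 are the five X-gap lengths
# of the eight-cysteine motif C-Xs1-C-Xs2-CC-Xs3-CXC-Xs4-C-Xs5-C).
# nterm/cterm are the observed flank lengths before Cys1 / after Cys8.
# "diagnostic" names the single gap whose value alone identifies the type,
# where one exists (the bold/underlined value of the published table).
# Type VII is absent from B. rapa; its envelope here is the minimal one used
# by the synthetic generator (27 residues between Cys6 and Cys7 is diagnostic).
I:
  s1: [9]
  s2: [13, 14, 16]
  s3: [19]
  s4: [19, 21, 22, 23, 24]
  s5: [9, 13]
  nterm: [3, 5, 9, 10]
  cterm: [1, 2, 4, 7, 15, 16, 20]
  diagnostic: {gap: s3, value: 19}
II:
  s1: [7]
  s2: [13, 14]
  s3: [8]
  s4: [21, 23, 25]
  s5: [5, 6]
  nterm: [0, 2, 7, 8, 9, 12, 13]
  cterm: [0, 2]
  diagnostic: {gap: s1, value: 7}
III:
  s1: [9]
  s2: [16]
  s3: [9]
  s4: [12]
  s5: [6]
  nterm: [2]
  cterm: [1, 4]
  diagnostic: {gap: s4, value: 12}
IV:
  s1: [9, 10]
  s2: [11, 15, 19]
  s3: [9, 12]
  s4: [19, 22, 23, 24]
  s5: [6, 7, 8]
  nterm: [2, 3, 8, 13]
  cterm: [0, 3, 7, 15]
  diagnostic: null
V:
  s1: [14]
  s2: [14]
  s3: [11, 12]
  s4: [24]
  s5: [10]
  nterm: [3]
  cterm: [6, 21]
  diagnostic: {gap: s1, value: 14}
VI:
  s1: [10]
  s2: [16, 17]
  s3: [9]
  s4: [22]
  s5: [9]
  nterm: [2, 9]
  cterm: [7, 8]
  diagnostic: null
VII:
  s1: [9]
  s2: [16]
  s3: [9]
  s4: [27]
  s5: [6]
  nterm: [2]
  cterm: [2]
  diagnostic: {gap: s4, value: 27}
VIII:
  s1: [6]
  s2: [14]
  s3: [12]
  s4: [25]
  s5: [8]
  nterm: [11]
  cterm: [21]
  diagnostic: {gap: s4, value: 25}
IX:
  s1: [13]
  s2: [15]
  s3: [9]
  s4: [22]
  s5: [6]
  nterm: [2, 19]
  cterm: [1, 4]
  diagnostic: {gap: s1, value: 13}
XI:
  s1: [8, 9]
  s2: [16, 18, 20]
  s3: [13]
  s4: [24, 25]
  s5: [9]
  nterm: [3, 9, 14]
  cterm: [0, 1, 2]
  diagnostic: {gap: s3, value: 13}
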