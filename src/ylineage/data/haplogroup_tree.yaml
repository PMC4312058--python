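# Rooted Y-SNP marker tree covering the haplogroups named in the Greenlandic
# and Danish analysis: the European lineages I-M170, R1a-M513, R1b-M343 and
# the Q-M242 branch with its circumpolar sub-lineages. Node order below is
# tree order (used when listing exclusions in paragroup labels).
#
# star_form: nodes whose paragroup is conventionally written with a star
# (e.g. Q*-M242) instead of an explicit exclusion list.
root: Y
nodes:
  Y:
    parent: null
    markers: []
  I-M170:
    parent: Y
    markers: [M170]
  R-M207:
    parent: Y
    markers: [M207, P224]
  R1a-M513:
    parent: R-M207
    markers: [M513]
  R1b-M343:
    parent: R-M207
    markers: [M343]
  Q-M242:
    parent: Y
    markers: [M242]
    star_form: true
  Q-MEH2:
    parent: Q-M242
    markers: [MEH2]
    star_form: true
  Q-NWT01:
    parent: Q-MEH2
    markers: [NWT01]
  Q-M265:
    parent: Q-NWT01
    markers: [M265]
  Q-M120:
    parent: Q-M265
    markers: [M120]
  Q-L54:
    parent: Q-MEH2
    markers: [L54]
  Q-M3:
    parent: Q-L54
    markers: [M3]
  Q-M19:
    parent: Q-M3
    markers: [M19]
  Q-M194:
    parent: Q-M3
    markers: [M194]
  Q-L663:
    parent: Q-M3
    markers: [L663]
  Q-SA01:
    parent: Q-M3
    markers: [SA01]
  Q-L766:
    parent: Q-M3
    markers: [L766]
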