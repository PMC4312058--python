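# Continental-origin grouping of haplogroup labels. Labels not listed fall
# through to "Other".
Inuit:
  - Q-NWT01 (xM265)
  - Q-M3 (xM19, M194, L663, SA01 and L766)
European:
  - I-M170
  - R1a-M513
  - R1b-M343
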