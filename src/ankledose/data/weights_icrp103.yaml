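# ICRP-103 tissue weighting factors used for the ankle region.
# Muscle and lymphatic nodes are the only leg tissues in the ICRP-103
# remainder set (13 tissues sharing w_T = 0.12); each remainder member
# contributes with weight 0.12 / 13.
schema: ankledose/weights-v1
w_R: 1.0
w_T:
  bone_marrow: 0.12
  bone_surface: 0.01
  skin: 0.01
  remainder: 0.12
remainder_members: [muscle, lymphatic_nodes]
remainder_count: 13
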