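quantity,siemens_msct,newtom_12x8,newtom_15x12,newtom_18x16,planmed_verity,shimadzu_ap_lat
bone_marrow,9.5,3.9,1.8,0.8,2.7,0.7
bone_surface,7.2,7.3,1.2,0.6,1.9,0.3
skin,3.1,2.2,0.7,0.3,0.9,0.3
lymphatic_nodes,0.9,0.8,0.2,0.1,0.3,0.1
muscle,0.6,0.1,0.1,0.1,0.1,0.1
effective_dose,21.4,14.3,4.0,1.9,6.0,1.5
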