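# Default fractions irradiated (f_i) for the ankle region and the
# dosimeters evaluating each sub-unit.
#
# Provenance of the fractions (see docs/methods.md):
#   bone marrow  - 1.1 % of whole-body marrow mass in the calf+foot region,
#                  split per bone (tibia 0.7 %, remaining bones to 0.4 %)
#   bone surface - 4.9 % of whole-body bone surface, per tuberosity site
#   skin         - 3.5 % of whole-body skin area (Du Bois), per skin site
#   muscle       - 0.9 % of a 28 kg whole-body muscle mass
#   lymph nodes  - 1 % of whole-body lymphatic nodes per ankle
#
# The lymphatic-nodes dosimeter list follows the phantom placements
# (dosimeters 12 and 17); the talus marrow dosimeter (15) carries no
# fraction and is deliberately unassigned by default.
schema: ankledose/fractions-v1
entries:
  - {tissue: bone_marrow, subunit: tibia,       f_i: 0.007, dosimeters: [1, 4, 7, 9], aggregation: mean_then_fraction}
  - {tissue: bone_marrow, subunit: fibula,      f_i: 0.001, dosimeters: [6, 11],      aggregation: mean_then_fraction}
  - {tissue: bone_marrow, subunit: navicular,   f_i: 0.001, dosimeters: [14],         aggregation: mean_then_fraction}
  - {tissue: bone_marrow, subunit: metatarsals, f_i: 0.001, dosimeters: [16],         aggregation: mean_then_fraction}
  - {tissue: bone_marrow, subunit: calcaneus,   f_i: 0.002, dosimeters: [18],         aggregation: mean_then_fraction}
  - {tissue: bone_surface, subunit: posterior_calcaneal_tuberosity, f_i: 0.049, dosimeters: [13], aggregation: per_site_fraction}
  - {tissue: bone_surface, subunit: calcaneal_tuberosity,           f_i: 0.049, dosimeters: [19], aggregation: per_site_fraction}
  - {tissue: skin, subunit: superior_extensor_retinaculum, f_i: 0.009, dosimeters: [8],  aggregation: per_site_fraction}
  - {tissue: skin, subunit: calcaneal_tendon,              f_i: 0.026, dosimeters: [10], aggregation: per_site_fraction}
  - {tissue: muscle,          subunit: muscle,          f_i: 0.009, dosimeters: [2, 3, 5, 20], aggregation: group_mean}
  - {tissue: lymphatic_nodes, subunit: lymphatic_nodes, f_i: 0.010, dosimeters: [12, 17],     aggregation: group_mean}
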