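# Default ankle phantom: six 25 mm layers (23-28) of an anthropomorphic
# RANDO leg phantom and the twenty MOSFET dosimeter placements.
schema: ankledose/phantom-v1
layers:
  - {index: 23, thickness_mm: 25.0, description: distal calf}
  - {index: 24, thickness_mm: 25.0, description: distal calf}
  - {index: 25, thickness_mm: 25.0, description: supramalleolar}
  - {index: 26, thickness_mm: 25.0, description: malleolar}
  - {index: 27, thickness_mm: 25.0, description: hindfoot}
  - {index: 28, thickness_mm: 25.0, description: midfoot}
dosimeters:
  - {dosimeter_no: 1,  layer: 23, site: Tibia,                          tissue: bone_marrow,     subunit: tibia}
  - {dosimeter_no: 2,  layer: 23, site: Peroneus brevis,                tissue: muscle,          subunit: muscle}
  - {dosimeter_no: 3,  layer: 23, site: Gastrocnemius,                  tissue: muscle,          subunit: muscle}
  - {dosimeter_no: 4,  layer: 24, site: Tibia,                          tissue: bone_marrow,     subunit: tibia}
  - {dosimeter_no: 5,  layer: 24, site: Tibialis anterior,              tissue: muscle,          subunit: muscle}
  - {dosimeter_no: 6,  layer: 25, site: Fibula,                         tissue: bone_marrow,     subunit: fibula}
  - {dosimeter_no: 7,  layer: 25, site: Tibia,                          tissue: bone_marrow,     subunit: tibia}
  - {dosimeter_no: 8,  layer: 26, site: Superior extensor retinaculum,  tissue: skin,            subunit: superior_extensor_retinaculum}
  - {dosimeter_no: 9,  layer: 26, site: Tibia,                          tissue: bone_marrow,     subunit: tibia}
  - {dosimeter_no: 10, layer: 26, site: Calcaneal tendon,               tissue: skin,            subunit: calcaneal_tendon}
  - {dosimeter_no: 11, layer: 26, site: Fibula,                         tissue: bone_marrow,     subunit: fibula}
  - {dosimeter_no: 12, layer: 26, site: Lymphatic vein,                 tissue: lymphatic_nodes, subunit: lymphatic_nodes}
  - {dosimeter_no: 13, layer: 27, site: Posterior calcaneal tuberosity, tissue: bone_surface,    subunit: calcaneal_tuberosity}
  - {dosimeter_no: 14, layer: 27, site: Navicular,                      tissue: bone_marrow,     subunit: navicular}
  - {dosimeter_no: 15, layer: 27, site: Talus,                          tissue: bone_marrow,     subunit: talus}
  - {dosimeter_no: 16, layer: 28, site: Metatarsals,                    tissue: bone_marrow,     subunit: metatarsals}
  - {dosimeter_no: 17, layer: 28, site: Lymphatic vein,                 tissue: lymphatic_nodes, subunit: lymphatic_nodes}
  - {dosimeter_no: 18, layer: 28, site: Calcaneus,                      tissue: bone_marrow,     subunit: calcaneus}
  - {dosimeter_no: 19, layer: 28, site: Calcaneal tuberosity,           tissue: bone_surface,    subunit: calcaneal_tuberosity}
  - {dosimeter_no: 20, layer: 28, site: Flexor digitorum brevis,        tissue: muscle,          subunit: muscle}
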