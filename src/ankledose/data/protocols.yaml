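# Exposure protocols of the compared devices (dot-decimal normalized).
# fov_length_mm is the scan length along the leg axis (for radiography,
# the field height); point-dose readings per protocol are supplied
# separately as readings CSVs.
schema: ankledose/protocols-v1
protocols:
  - {name: siemens_msct,    modality: MSCT,        kVp: 120, mAs: 54.0, fov_length_mm: 160, scan_angle_deg: 360}
  - {name: newtom_12x8,     modality: CBCT,        kVp: 110, mAs: 59.0, fov_length_mm: 80,  scan_angle_deg: 360}
  - {name: newtom_15x12,    modality: CBCT,        kVp: 110, mAs: 5.3,  fov_length_mm: 120, scan_angle_deg: 360}
  - {name: newtom_18x16,    modality: CBCT,        kVp: 110, mAs: 2.3,  fov_length_mm: 160, scan_angle_deg: 360}
  - {name: planmed_verity,  modality: CBCT,        kVp: 90,  mAs: 48.0, fov_length_mm: 160, scan_angle_deg: 210}
  - {name: shimadzu_ap_lat, modality: radiography, kVp: 57,  mAs: 16.0, fov_length_mm: 160, projections: [AP, LAT]}
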