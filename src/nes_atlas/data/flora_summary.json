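{
  "comment": "Published flora-level summary tallies for the New Caledonian narrow-endemism assessment; inputs to arithmetic consistency summaries.",
  "nes_class_counts": {"NES1": 309, "NES2": 193, "NES3": 133},
  "n_assessed_species": 2930,
  "n_nes_with_iucn_assessment": 150,
  "eco_group_sizes": {"G1": 43, "G2": 225, "G3": 284},
  "n_precisely_located_species": 552
}
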