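{
  "_comment": "Donor assignments for tissues without published dielectric measurements: unknown tissue -> table row with similar composition.",
  "Cerebellum White Matter": "Brain (White Matter)",
  "Vermis Grey Matter": "Cerebellum",
  "Meninges": "Dura",
  "Pancreas": "Liver",
  "Prostate": "Testis",
  "Esophagus": "Stomach",
  "Trachea and main Bronchi": "Trachea",
  "Spinal cord": "Nerve",
  "SAT (Subcutaneous fat)": "Fat",
  "Connective tissue": "Connective Tissue",
  "Eye (Aqueous Humour)": "Eye (Vitreous Humor)"
}
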