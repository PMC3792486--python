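{
  "format": "neurofba-boundary/1",
  "description": "Arteriovenous differences defining the blood-exchange rates r_j = Q/F * (Ca - Cv), in mM, with Q in ml/min/g and F dimensionless; resulting rates in umol/min per g tissue.",
  "Q": 0.55,
  "F": 1.0,
  "sigma_default": 0.005,
  "sigma_loose": 10.0,
  "entries": {
    "Glc": {"difference": 0.54, "pm": 0.05},
    "Lac": {"difference": -0.18, "pm": 0.02},
    "O2": {"arterial": 9.15, "pm": 0.5, "venous": "estimated"},
    "CO2": {"arterial": 23.0, "pm": 1.0, "venous": "estimated"},
    "NH4+": {"difference": 0.0, "pm": 0.2},
    "Leu": {"difference": 0.0, "pm": 0.1},
    "Gln": {"difference": 0.0, "pm": 0.1},
    "Ala": {"difference": 0.0, "pm": null,
            "note": "no printed arteriovenous entry (the table defines only non-vanishing exchange rates); the alanine blood equation keeps the default model-equation sigma"}
  }
}
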