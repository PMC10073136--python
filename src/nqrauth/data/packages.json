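{
  "plastic": {"standoff_m": 0.0001, "conductive_attenuation": 1.0},
  "thin_paper": {"standoff_m": 0.0002, "conductive_attenuation": 1.0},
  "thick_paper": {"standoff_m": 0.0005, "conductive_attenuation": 1.0},
  "electrostatic": {"standoff_m": 0.001, "conductive_attenuation": 0.85},
  "cardboard": {"standoff_m": 0.003, "conductive_attenuation": 1.0},
  "bubble_wrap": {"standoff_m": 0.004, "conductive_attenuation": 1.0}
}
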