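{
  "cardboard": {"slope": 0.00086, "offset": 0.0386, "q_min": 6.0, "q_max": 18.0},
  "thin_paper": {"slope": 0.0040, "offset": 0.0273, "q_min": 6.0, "q_max": 18.0},
  "thick_paper": {"slope": 0.0049, "offset": 0.0174, "q_min": 6.0, "q_max": 18.0},
  "plastic": {"slope": 0.0070, "offset": 0.0013, "q_min": 6.0, "q_max": 18.0},
  "bubble_wrap": {"slope": 0.0037, "offset": 0.0076, "q_min": 6.0, "q_max": 18.0},
  "electrostatic": {"slope": 0.0037, "offset": 0.0330, "q_min": 6.0, "q_max": 18.0}
}
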