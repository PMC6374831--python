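{
  "name": "Visible Chinese Human head reference",
  "percentages": {"CSF": 37.65, "GM": 27.08, "WM": 12.35, "SKULL": 12.81},
  "gm_wm_ratio": 2.22,
  "literature_ratios": {"IS": 2.03, "Ge": 1.5}
}
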