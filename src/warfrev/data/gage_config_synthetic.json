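{
  "label": "SYNTHETIC placeholder coefficients for testing only - NOT the published clinical equation. Coefficients loosely track the synthetic cohort generator's dose model (deliberately coarsened) so the comparator behaves like a reasonable-but-imperfect clinical equation. Transcribe the published coefficients into a config of this shape for real use.",
  "intercept": 1.94,
  "coefficients": {
    "bsa": 0.65,
    "age": -0.0075,
    "target_inr": 0.25,
    "smoker": 0.05,
    "african_american": 0.15,
    "amiodarone": -0.40,
    "vte_indication": 0.05
  },
  "age_unit": "years",
  "link": "log",
  "output_unit": "mg/wk",
  "bsa_formula": "mosteller"
}
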