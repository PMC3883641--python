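{
  "rho_fat": 9440.0,
  "rho_lean": 1807.0,
  "gamma_fat": 3.2,
  "gamma_lean": 22.0,
  "rmr_constant": 500.0,
  "activity_coeff": 9.0,
  "tef_fraction": 0.10,
  "at_beta": 0.14,
  "at_tau_days": 14.0,
  "forbes_c": 10.4,
  "relative_sd": 0.05,
  "units": {
    "rho_fat": "kcal/kg",
    "rho_lean": "kcal/kg",
    "gamma_fat": "kcal/kg/day",
    "gamma_lean": "kcal/kg/day",
    "rmr_constant": "kcal/day",
    "activity_coeff": "kcal/kg/day",
    "at_tau_days": "day",
    "forbes_c": "kg"
  }
}
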