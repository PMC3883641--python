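{
  "goods": ["milk", "ssb", "juice", "coffee", "tea", "other"],
  "alpha": [0.06, 0.02, 0.012, 0.008, 0.02, 0.88],
  "expenditure_elasticity": [1.2, 1.5, 1.6, 1.2, 1.1, null],
  "lambda": [0.002, 0.001, 0.0008, 0.0004, 0.0006, null],
  "own_price_elasticity_non_ssb": {
    "milk": -0.35,
    "juice": -0.80,
    "coffee": -0.60,
    "tea": -0.50
  },
  "gamma_cross_non_ssb": {
    "milk,juice": 0.0002,
    "milk,coffee": 0.0002,
    "milk,tea": 0.0008,
    "juice,coffee": 0.0001,
    "juice,tea": 0.0003,
    "coffee,tea": 0.0002
  },
  "median_prices": {
    "milk": 0.030,
    "ssb": 0.045,
    "juice": 0.080,
    "coffee": 0.070,
    "tea": 0.050,
    "other": 1.0
  },
  "cohort_price_shift": {"urban": 0.03, "income_low": -0.02, "income_high": 0.02},
  "outlay_median": 60.0,
  "outlay_log_sd": 0.25,
  "price_log_sd": 0.09,
  "price_band": 0.175,
  "other_price_band": 0.05,
  "share_noise_sd": 0.003,
  "censoring": {
    "consume_prob": {"milk": 0.95, "ssb": 0.65, "juice": 0.45, "coffee": 0.55, "tea": 0.95},
    "coefficients": {
      "household_size": 0.05,
      "age_head": -0.01,
      "availability": 0.8,
      "urban": 0.2,
      "income_mid": 0.1,
      "income_high": 0.2
    }
  }
}
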