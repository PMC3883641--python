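beverage,kcal_per_gram,ci_low,ci_high
milk,0.64,0.55,0.73
ssb,0.42,0.38,0.46
juice,0.45,0.40,0.50
coffee,0.35,0.25,0.45
tea,0.30,0.20,0.40
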