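beverage,gl_per_kcal,ci_low,ci_high
milk,0.0311,0.0235,0.0387
ssb,0.1584,0.1408,0.1759
juice,0.0870,0.0758,0.0981
coffee,0.0919,0.0850,0.0989
tea,0.0553,0.0497,0.0608
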