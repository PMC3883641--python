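segment,level,beverage,elasticity,ci_low,ci_high
income,low,milk,0.055,0.013,0.096
income,low,ssb,-0.90,-0.93,-0.86
income,low,juice,0.32,0.31,0.36
income,low,coffee,0.0016,-0.077,0.051
income,low,tea,0.10,0.062,0.131
income,mid,milk,0.046,0.010,0.083
income,mid,ssb,-0.96,-1.00,-0.92
income,mid,juice,0.30,0.25,0.35
income,mid,coffee,0.0054,-0.058,0.084
income,mid,tea,0.14,0.12,0.18
income,high,milk,0.046,0.010,0.083
income,high,ssb,-0.96,-1.00,-0.92
income,high,juice,0.30,0.25,0.35
income,high,coffee,0.0054,-0.058,0.084
income,high,tea,0.14,0.12,0.18
residence,urban,milk,0.049,0.010,0.087
residence,urban,ssb,-0.94,-0.98,-0.90
residence,urban,juice,0.31,0.27,0.35
residence,urban,coffee,0.0041,-0.064,0.073
residence,urban,tea,0.13,0.098,0.16
residence,rural,milk,0.049,0.012,0.087
residence,rural,ssb,-0.94,-0.98,-0.90
residence,rural,juice,0.31,0.27,0.35
residence,rural,coffee,0.0041,-0.064,0.073
residence,rural,tea,0.13,0.098,0.16
overall,overall,milk,0.049,0.011,0.087
overall,overall,ssb,-0.94,-0.98,-0.90
overall,overall,juice,0.31,0.27,0.35
overall,overall,coffee,0.0041,-0.064,0.073
overall,overall,tea,0.13,0.098,0.16
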