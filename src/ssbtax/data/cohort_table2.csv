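segment,level,milk_kcal,milk_sd,ssb_kcal,ssb_sd,juice_kcal,juice_sd,coffee_kcal,coffee_sd,tea_kcal,tea_sd,overweight_pct,overweight_sd,diabetes_incidence,diabetes_incidence_sd
age,25-44,200,5,52,1,36,0.3,19,2,83,5,34,8,156,35
age,45-65,226,5,37,1,30,0.7,24,2,81,6,48,11,379,50
sex,male,220,4,50,1,34,0.3,21,2,85,5,32,8,507,46
sex,female,193,5,42,1,34,0.5,21,2,79,6,46,10,103,44
income,low,139,6,44,1,29,0.8,17,2,82,6,11,2,105,67
income,mid,173,6,48,1,40,0.5,26,2,81,6,16,4,157,50
income,high,220,6,47,1,32,0.7,19,2,85,6,43,10,350,45
residence,urban,223,6,48,1,38,2,25,2,83,6,48,11,372,50
residence,rural,187,6,45,2,28,2,16,2,82,7,21,5,242,42
overall,overall,207,5,46,1,34,0.4,21,2,82,5,38,8,307,45
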