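# Inflammatory effect scores for the 35-parameter dietary inflammatory index used here.
# Effect scores follow the literature-derived convention (positive = pro-inflammatory,
# negative = anti-inflammatory). The 35-parameter subset and the global reference
# means/SDs are a reconstruction assembled for this package (the exact subset used in
# any given FFQ study varies with the instrument); ref_mean/ref_sd feed the optional
# "global" standardization mode only.
parameter,unit,effect_score,ref_mean,ref_sd
energy,kcal/day,0.180,2056.0,338.0
carbohydrate,g/day,0.097,272.2,40.0
protein,g/day,0.021,79.4,13.9
total_fat,g/day,0.298,71.4,19.4
fiber,g/day,-0.663,18.8,4.9
cholesterol,mg/day,0.110,279.4,51.2
saturated_fat,g/day,0.373,28.6,8.0
mufa,g/day,-0.009,27.0,6.1
pufa,g/day,-0.337,13.88,3.76
n3_fatty_acids,g/day,-0.436,1.06,1.06
n6_fatty_acids,g/day,-0.159,10.8,7.5
trans_fat,g/day,0.229,3.15,3.75
alcohol,g/day,-0.278,13.98,3.72
vitamin_a,µg/day,-0.401,983.9,518.6
beta_carotene,µg/day,-0.584,3718.0,1720.0
vitamin_b6,mg/day,-0.365,1.47,0.74
vitamin_b12,µg/day,0.106,5.15,2.70
vitamin_c,mg/day,-0.424,118.2,43.46
vitamin_d,µg/day,-0.446,6.26,2.21
vitamin_e,mg/day,-0.419,8.73,1.49
thiamin,mg/day,-0.098,1.70,0.66
riboflavin,mg/day,-0.068,1.70,0.79
niacin,mg/day,-0.246,25.90,11.77
folic_acid,µg/day,-0.190,273.0,70.0
iron,mg/day,0.032,13.35,3.71
magnesium,mg/day,-0.484,310.1,139.4
zinc,mg/day,-0.313,9.84,2.19
selenium,µg/day,-0.191,67.0,25.1
caffeine,g/day,-0.110,8.05,6.67
garlic,g/day,-0.412,4.35,2.90
ginger,g/day,-0.453,59.0,63.2
onion,g/day,-0.301,35.9,18.4
green_black_tea,g/day,-0.536,1.69,1.53
saffron,g/day,-0.140,0.37,1.22
turmeric,mg/day,-0.785,533.6,754.3
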