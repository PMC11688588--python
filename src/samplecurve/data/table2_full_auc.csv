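dataset,xgb,rf,lr,nn
Cardio,0.802,0.796,0.784,0.795
Diabetes130,0.662,0.661,0.654,0.661
NoShow,0.608,0.609,0.596,0.603
BreastTumor,0.777,0.780,0.682,0.730
Diabetes,0.829,0.822,0.822,0.826
COVID-19,0.664,0.661,0.642,0.661
LOS,0.917,0.915,0.898,0.901
CDC Heart Disease (2020),0.815,0.810,0.810,0.809
CDC Heart Disease (2022),0.815,0.801,0.809,0.801
Heart,0.965,0.963,0.949,0.962
Hepatitis,0.979,0.976,0.939,0.974
Lymph,0.957,0.957,0.934,0.956
Pharynx,0.858,0.858,0.843,0.856
Cholesterol,0.736,0.728,0.669,0.714
Dermatology,0.859,0.857,0.823,0.852
PBC,0.850,0.850,0.788,0.823
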