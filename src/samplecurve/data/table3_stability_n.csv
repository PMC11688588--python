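dataset,xgb,rf,lr,nn
Cardio,4341,1476,363,4349
Diabetes130,9623,3544,1822,16823
NoShow,12114,2241,742,8084
BreastTumor,19668,17383,558,28424
Diabetes,9306,2261,1140,8556
COVID-19,7026,4750,543,4241
LOS,18239,15381,2555,14085
CDC Heart Disease (2020),15177,4995,2243,10510
CDC Heart Disease (2022),30534,16355,6768,25120
Heart,960,250,204,1824
Hepatitis,3513,3265,425,15302
Lymph,1409,1992,276,4470
Pharynx,10296,2488,317,5260
Cholesterol,65556,140499,1368,180835
Dermatology,7979,3103,1696,47489
PBC,31897,71194,650,53453
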