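dataset,source,full_n,minority_pct,n_features,pct_core_linear,pct_continuous,nonlinearity
Cardio,OpenML,70000,50,11,100,45.5,1.8
Diabetes130,OpenML,101766,46.1,35,45.7,20,0.8
NoShow,OpenML,110527,20.2,8,25,12.5,1.2
BreastTumor,OpenML,116640,34.6,9,44.4,33.3,9.5
Diabetes,UCI,253680,13.9,21,85.7,19,0.7
COVID-19,OpenML,263007,39,16,37.5,6.25,2.2
LOS,OpenML,318438,2.1,11,36.4,27.3,1.9
CDC Heart Disease (2020),Kaggle,319795,4.4,17,76.5,23.5,0.5
CDC Heart Disease (2022),Kaggle,394509,8.6,39,59,15.4,0.6
Heart,OpenML,1000000,44.4,13,92.3,46.2,1.6
Hepatitis,OpenML,1000000,20.8,19,94.7,31.6,4.0
Lymph,OpenML,1000000,45.7,18,83.3,5.6,2.3
Pharynx,OpenML,1000000,25.6,11,72.2,18.2,1.5
Cholesterol,OpenML,1000000,16.5,13,61.5,30.8,6.7
Dermatology,OpenML,1000000,13.2,33,84.8,3,3.6
PBC,OpenML,1000000,17.8,18,83.3,55.6,6.2
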