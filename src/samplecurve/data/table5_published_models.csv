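algorithm,predictor,estimate,ci_low,ci_high,pseudo_r2_adj
xgb,intercept,121967,57883,262108,0.845
xgb,minority_pct,0.956,0.946,0.967,0.845
xgb,separability,0.952,0.934,0.970,0.845
xgb,nonlinearity_high,3.091,2.011,4.922,0.845
rf,intercept,26872,8118,92378,0.808
rf,minority_pct,0.957,0.940,0.975,0.808
rf,separability,0.975,0.947,1.004,0.808
rf,nonlinearity_high,12.298,5.826,28.791,0.808
lr,intercept,1801,904,3809,0.798
lr,minority_pct,0.968,0.957,0.979,0.798
lr,n_features,1.054,1.034,1.076,0.798
lr,pct_core_linear,0.988,0.980,0.996,0.798
nn,intercept,36819,18691,76970,0.665
nn,minority_pct,0.976,0.957,0.996,0.665
nn,pct_continuous,0.973,0.950,0.997,0.665
nn,nonlinearity_high,10.209,4.274,26.569,0.665
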