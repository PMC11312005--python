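noise_intensity,algorithm,material,value
0.001,Noisy,CSF,0.131
0.001,Noisy,GM,0.128
0.001,Noisy,WM,0.123
0.001,Gaussian,CSF,0.085
0.001,Gaussian,GM,0.085
0.001,Gaussian,WM,0.077
0.001,Wiener,CSF,0.063
0.001,Wiener,GM,0.057
0.001,Wiener,WM,0.052
0.001,TV,CSF,0.075
0.001,TV,GM,0.071
0.001,TV,WM,0.066
0.001,FNLM,CSF,0.020
0.001,FNLM,GM,0.017
0.001,FNLM,WM,0.009
0.005,Noisy,CSF,0.276
0.005,Noisy,GM,0.270
0.005,Noisy,WM,0.263
0.005,Gaussian,CSF,0.175
0.005,Gaussian,GM,0.170
0.005,Gaussian,WM,0.166
0.005,Wiener,CSF,0.140
0.005,Wiener,GM,0.131
0.005,Wiener,WM,0.126
0.005,TV,CSF,0.211
0.005,TV,GM,0.205
0.005,TV,WM,0.200
0.005,FNLM,CSF,0.021
0.005,FNLM,GM,0.018
0.005,FNLM,WM,0.015
0.01,Noisy,CSF,0.403
0.01,Noisy,GM,0.384
0.01,Noisy,WM,0.376
0.01,Gaussian,CSF,0.254
0.01,Gaussian,GM,0.249
0.01,Gaussian,WM,0.238
0.01,Wiener,CSF,0.211
0.01,Wiener,GM,0.191
0.01,Wiener,WM,0.190
0.01,TV,CSF,0.337
0.01,TV,GM,0.319
0.01,TV,WM,0.312
0.01,FNLM,CSF,0.034
0.01,FNLM,GM,0.021
0.01,FNLM,WM,0.021
0.05,Noisy,CSF,0.722
0.05,Noisy,GM,0.754
0.05,Noisy,WM,0.729
0.05,Gaussian,CSF,0.453
0.05,Gaussian,GM,0.483
0.05,Gaussian,WM,0.463
0.05,Wiener,CSF,0.356
0.05,Wiener,GM,0.383
0.05,Wiener,WM,0.368
0.05,TV,CSF,0.659
0.05,TV,GM,0.690
0.05,TV,WM,0.667
0.05,FNLM,CSF,0.084
0.05,FNLM,GM,0.095
0.05,FNLM,WM,0.088
0.1,Noisy,CSF,0.913
0.1,Noisy,GM,0.876
0.1,Noisy,WM,0.882
0.1,Gaussian,CSF,0.579
0.1,Gaussian,GM,0.575
0.1,Gaussian,WM,0.565
0.1,Wiener,CSF,0.436
0.1,Wiener,GM,0.425
0.1,Wiener,WM,0.436
0.1,TV,CSF,0.852
0.1,TV,GM,0.818
0.1,TV,WM,0.824
0.1,FNLM,CSF,0.110
0.1,FNLM,GM,0.106
0.1,FNLM,WM,0.111
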