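noise_intensity,algorithm,material,value
0.001,Noisy,CSF,0.652
0.001,Noisy,GM,0.793
0.001,Noisy,WM,0.486
0.001,Gaussian,CSF,0.994
0.001,Gaussian,GM,1.199
0.001,Gaussian,WM,0.754
0.001,Wiener,CSF,1.351
0.001,Wiener,GM,1.727
0.001,Wiener,WM,1.062
0.001,TV,CSF,1.138
0.001,TV,GM,1.416
0.001,TV,WM,0.881
0.001,FNLM,CSF,5.278
0.001,FNLM,GM,7.458
0.001,FNLM,WM,6.588
0.005,Noisy,CSF,0.289
0.005,Noisy,GM,0.358
0.005,Noisy,WM,0.264
0.005,Gaussian,CSF,0.448
0.005,Gaussian,GM,0.549
0.005,Gaussian,WM,0.406
0.005,Wiener,CSF,0.581
0.005,Wiener,GM,0.710
0.005,Wiener,WM,0.531
0.005,TV,CSF,0.376
0.005,TV,GM,0.462
0.005,TV,WM,0.343
0.005,FNLM,CSF,3.806
0.005,FNLM,GM,4.982
0.005,FNLM,WM,3.766
0.01,Noisy,CSF,0.207
0.01,Noisy,GM,0.261
0.01,Noisy,WM,0.160
0.01,Gaussian,CSF,0.331
0.01,Gaussian,GM,0.406
0.01,Gaussian,WM,0.253
0.01,Wiener,CSF,0.406
0.01,Wiener,GM,0.523
0.01,Wiener,WM,0.312
0.01,TV,CSF,0.251
0.01,TV,GM,0.316
0.01,TV,WM,0.193
0.01,FNLM,CSF,2.740
0.01,FNLM,GM,4.134
0.01,FNLM,WM,2.615
0.05,Noisy,CSF,0.046
0.05,Noisy,GM,0.053
0.05,Noisy,WM,0.044
0.05,Gaussian,CSF,0.076
0.05,Gaussian,GM,0.083
0.05,Gaussian,WM,0.074
0.05,Wiener,CSF,0.096
0.05,Wiener,GM,0.104
0.05,Wiener,WM,0.081
0.05,TV,CSF,0.051
0.05,TV,GM,0.058
0.05,TV,WM,0.049
0.05,FNLM,CSF,0.397
0.05,FNLM,GM,0.488
0.05,FNLM,WM,0.526
0.1,Noisy,CSF,0.076
0.1,Noisy,GM,0.044
0.1,Noisy,WM,0.028
0.1,Gaussian,CSF,0.117
0.1,Gaussian,GM,0.066
0.1,Gaussian,WM,0.042
0.1,Wiener,CSF,0.157
0.1,Wiener,GM,0.085
0.1,Wiener,WM,0.045
0.1,TV,CSF,0.081
0.1,TV,GM,0.047
0.1,TV,WM,0.030
0.1,FNLM,CSF,0.563
0.1,FNLM,GM,0.471
0.1,FNLM,WM,0.183
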