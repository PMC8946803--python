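patient,sensitivity,specificity,ppv,npv,auc,mcc,tumor_free
1,0.91,0.55,0.79,0.77,0.76,0.51,0
2,-,0.00,0,-,-,-,1
3,-,0.55,0,1.00,-,-,1
4,-,0.99,0,1.00,-,-,1
6,0.55,0.87,0.42,0.92,0.79,0.38,0
7,0.66,0.79,0.64,0.81,0.78,0.45,0
8,-,1.00,0,1.00,-,-,1
9,0.95,0.67,0.05,1.00,0.84,0.18,0
10,0.85,0.88,0.30,0.99,0.89,0.46,0
11,0.91,0.72,0.98,0.40,0.89,0.49,0
Mean,0.81,0.70,0.53,0.82,0.83,0.41,
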