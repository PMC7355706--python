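study_id,ka_per_h,k10_per_h,k12_per_h,k21_per_h,v_over_f_L
1,1.131,0.079,1.025,0.032,474
2,0.962,0.2975,0.392,0.325,1791
3,0.509,0.116,0.407,0.001,1418
4,0.756,0.102,0.648,0.005,1342
5,0.819,0.088,0.726,0.007,1531
6,1.149,0.061,1.035,0.042,1083
7,1.434,0.684,0.669,0.098,859
8,0.798,0.797,9.869E-06,0.062,1342
9,0.726,0.728,9.515E-06,0.061,1526
10,0.837,0.181,0.700,4.933E-06,1081
11,0.511,0.084,0.434,0.002,1112
12,0.523,0.039,0.518,0.010,820
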