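patient,n_seizures,data_hours,sensitivity_pct,fdr_uninteresting_per_h,fdr_interesting_per_h,mean_latency_s
1,3,2.48,66.67,4.4,0.40,7.21
2,2,5.16,100,2.52,0.39,25.03
3,4,5.10,75,0.19,0.19,8.72
4,3,5.87,100,1,0.17,27.43
5,2,3.81,100,0.26,0.26,23.97
6,2,4.13,100,0.72,0,12.64
7,2,3.91,100,1.02,0,17.46
8,2,3.49,100,1.43,0.57,55.46
9,5,8.83,100,1.24,0.34,-24.92
11,3,4.92,100,1.01,0.40,-6.84
12,4,7.87,75,2.16,0.50,21.04
13,2,3.92,100,0.51,0,-37.69
14,3,4.91,100,0.61,0.20,40.14
15,2,5.92,100,0,0,27.37
16,4,9.83,100,3.86,1.01,5.64
17,5,14.59,100,0.06,0,23.52
18,1,1.96,100,1.02,0,0.31
19,2,5.92,100,0.33,0,1.33
20,3,6.87,100,0.43,0.14,27.07
21,2,2.96,100,4.72,0.67,61.42
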