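scenario,dose,pi_T,pi_E
1,1,0.05,0.38
1,2,0.12,0.55
1,3,0.27,0.71
1,4,0.50,0.83
2,1,0.38,0.77
2,2,0.52,0.82
2,3,0.67,0.86
2,4,0.79,0.89
3,1,0.02,0.12
3,2,0.07,0.25
3,3,0.15,0.45
3,4,0.31,0.67
4,1,0.05,0.18
4,2,0.11,0.55
4,3,0.25,0.79
4,4,0.46,0.86
5,1,0.03,0.18
5,2,0.08,0.25
5,3,0.18,0.33
5,4,0.38,0.43
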