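age_group,multiplier,time_shift
15-19,1.7476,1.16
20-24,1.277,2.71
25-29,1.1433,4.4
30-34,1.0565,6.62
35-39,0.9978,9.73
40-44,0.9607,13.7
45-49,0.9355,18.13
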