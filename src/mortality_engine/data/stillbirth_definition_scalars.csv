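definition,scalar
20wk,0.74
22wk,0.80
24wk,0.86
26wk,0.93
28wk,1.00
500g,0.87
1000g,1.10
none,0.95
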