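age_group,weight
early_neonatal,0.0003339
late_neonatal,0.0010007
post_neonatal,0.01606018
1_to_4,0.07117865
5_to_9,0.08687394
10_to_14,0.08597421
15_to_19,0.0846746
20_to_24,0.08217535
25_to_29,0.07927622
30_to_34,0.07607718
35_to_39,0.07147856
40_to_44,0.06588024
45_to_49,0.06038189
50_to_54,0.05368389
55_to_59,0.04548635
60_to_64,0.03718884
65_to_69,0.02959112
70_to_74,0.02209337
75_to_79,0.01519544
80_to_84,0.00909727
85_to_89,0.00419874
90_to_94,0.00159952
95_plus,0.00049985
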