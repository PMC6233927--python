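scheme	region	n_sites	rate_low	rate_high
rieux	HVS1+HVS2	698	56.40	100.76
rieux	PC1+PC2	7565	1.43	2.34
rieux	PC3	3776	6.42	10.19
rieux	rRNA+tRNA	4031	1.89	3.17
oversti	HVS1+HVS2	1122	31.23	72.53
oversti	PC1+PC2	7565	2.92	6.00
oversti	PC3	3776	4.80	10.53
oversti	rRNA+tRNA	4031	2.35	5.75
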