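ncrf_class	FC_M	CER_M	HIP_M	FC_F	CER_F	HIP_F
tRF	57307.00	17374.36	37031.61	31510.58	12117.04	28367.62
rRF	42.00	23.18	17.39	10.19	0.00	81.74
snRF	87.00	117.33	893.96	24.46	196.79	746.73
snoRF	989.00	2056.82	1219.20	815.23	2178.15	1200.29
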