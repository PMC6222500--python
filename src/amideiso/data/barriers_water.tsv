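compound	dE_anti_plus	dG_anti_plus	dE_anti_minus	dG_anti_minus	dE_syn_plus	dG_syn_plus	dE_syn_minus	dG_syn_minus	dG_eff
N0000	19.18	13.82	19.18	13.74	24.29	20.07	ND	ND	13.74
N0010	25.40	20.48	19.03	13.67	29.42	23.23	24.23	20.47	13.67
N0100	22.45	18.28	20.66	16.24	23.31	18.6	26.09	19.91	16.24
N0110	25.13	21.06	19.32	13.46	22.23	19.06	20.47	16.61	13.46
N011’0	26.44	20.83	26.55	20.67	23.39	18.55	26.51	21.71	18.55
N1000	22.30	16.89	22.35	16.85	ND	ND	23.86	19.40	16.85
N1010	26.60	20.05	19.00	12.72	29.60	23.96	24.29	19.71	12.72
N1100	22.54	14.06	23.71	16.92	26.50	19.28	23.04	16.86	14.06
N1110	29.46	21.96	24.53	19.22	29.24	24.21	30.37	23.98	19.22
N111’0	23.15	14.50	27.71	21.34	26.65	19.74	23.78	17.50	14.50
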