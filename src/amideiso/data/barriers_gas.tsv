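compound	dE_anti_plus	dG_anti_plus	dE_anti_minus	dG_anti_minus	dE_syn_plus	dG_syn_plus	dE_syn_minus	dG_syn_minus	dG_eff
N0000	19.53	13.70	19.53	13.72	25.46	19.91	25.26	19.84	13.70
N0010	24.22	18.34	19.34	11.93	25.22	17.86	27.99	20.23	11.93
N0100	20.96	13.40	20.51	12.43	26.30	18.63	25.26	20.38	12.43
N0110	25.64	18.72	19.76	12.34	23.98	17.63	28.18	22.10	12.34
N011’0	19.99	12.91	24.92	17.54	27.33	19.06	29.92	22.79	12.91
N1000	19.55	11.03	19.82	11.09	ND	ND	25.09	19.31	11.03
N1010	24.33	17.92	20.10	14.82	24.95	17.65	27.80	22.20	14.82
N1100	21.54	12.90	20.59	13.14	26.61	19.13	25.40	17.49	12.90
N1110	26.08	17.27	20.15	11.17	28.29	20.62	34.39	28.17	11.17
N111’0	21.43	12.59	26.18	17.45	30.79	22.72	23.68	14.51	12.59
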