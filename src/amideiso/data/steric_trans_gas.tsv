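compound	optE	n_tBu_N	n_tBu_C	AddE	stE
N0000t	−333,806.071			−333,806.071	0
N0010t	−432,516.46		1	−432,518.205	1.745
N0100t	−432,515.901		1	−432,518.205	2.304
N0110t	−531,225.709		2	−531,230.339	4.63
N011’0t	−531,225.494		2	−531,230.339	4.845
N1000t	−432,514.375	1		−432,515.202	0.827
N1010t	−531,224.575	1	1	−531,227.336	2.761
N1100t	−531,222.518	1	1	−531,227.336	4.818
N1110t	−629,932.315	1	2	−629,939.47	7.155
N111’0t	−629,931.92	1	2	−629,939.47	7.55
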