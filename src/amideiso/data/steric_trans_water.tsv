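compound	solvationE	optE	n_tBu_N	n_tBu_C	AddE	stE
N0000t	−16.33	−381,811.506			−381,811.506	0
N0010t	−16.85	−480,519.643		1	−480,523.468	3.825
N0100t	−14.86	−480,518.077		1	−480,523.468	5.391
N0110t	−16.1	−579,224.507		2	−579,235.43	10.923
N011’0t	−12.66	−579,225.518		2	−579,235.43	9.912
N1000t	−11.16	−480,518.478	1		−480,519.152	0.674
N1010t	−15.97	−579,226.192	1	1	−579,231.114	4.922
N1100t	−13.47	−579,222.324	1	1	−579,231.114	8.79
N1110t	−11.49	−677,932.254	1	2	−677,943.076	10.822
N111’0t	−11.34	−677,929.486	1	2	−677,943.076	13.59
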