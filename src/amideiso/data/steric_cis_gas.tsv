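compound	optE	n_tBu_N	n_tBu_C	AddE	stE
N0000c	−333,801.441			−333,801.441	0
N0010c	−432,511.233		1	−432,513.575	2.342
N0100c	−432,510.785		1	−432,513.575	2.79
N0110c	−531,219.543		2	−531,225.709	6.166
N011’0c	−531,220.53		2	−531,225.709	5.179
N1000c	−432,509.352	1		−432,510.572	1.22
N1010c	−531,218.91	1	1	−531,222.706	3.796
N1100c	−531,217.348	1	1	−531,222.706	5.358
N1110c	−629,924.792	1	2	−629,934.84	10.048
N111’0c	−629,924.4	1	2	−629,934.84	10.44
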