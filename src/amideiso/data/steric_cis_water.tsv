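compound	optE	n_tBu_N	n_tBu_C	AddE	stE
N0000c	−333,819.556			−333,819.556	0
N0010c	−432,526.761		1	−432,531.518	4.757
N0100c	−432,526.055		1	−432,531.518	5.463
N0110c	−531,233.207		2	−531,243.48	10.273
N011’0c	−531,232.806		2	−531,243.48	10.674
N1000c	−432,525.775	1		−432,527.202	1.427
N1010c	−531,232.932	1	1	−531,239.164	6.232
N1100c	−531,228.49	1	1	−531,239.164	10.674
N1110c	−629,934.673	1	2	−629,951.126	16.453
N111’0c	−629,934.711	1	2	−629,951.126	16.415
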