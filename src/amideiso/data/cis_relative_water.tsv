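compound	solvationE	psiN	omega	phiC	psiC	dE	dG
N0000c	−19.43	179.5	0.1	−179.6	179.7	2.03	2.1
N0010c	−17.85	−163.8	−0.6	−129.8	144.4	2.97	2.9
N0100c	−16.88	127.5	−2.1	−176.4	−177.4	2.11	2.3
N0110c	−15.67	128.2	4.3	−80.8	143.6	1.38	1.7
N011’0c	−14.7	130.7	8.3	133.4	−141.9	2.80	2.4
N1000c	−19.86	−174.0	0.7	−167.2	178.3	2.79	2.9
N1010c	−18.63	−159.0	0.0	−128.3	143.1	3.34	3.1
N1100c	−14.35	140.1	0.7	113.8	−163.8	3.92	3.7
N1110c	−11.87	134.6	−5.4	−94.3	138.8	7.66	8.1
N111’0c	−11.76	141.2	9.5	109.1	−147.5	4.86	4.94
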