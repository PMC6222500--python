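compound	psiN	omega	phiC	psiC	dE	dG
N0000c	179.9	0.1	−179.9	179.8	4.63	4.92
N0010c	−176.7	−6.1	−115.2	132.8	5.23	5.14
N0100c	130.7	−2.4	−178.5	−179.3	5.12	4.92
N0110c	130.0	−8.5	−80.9	131.9	6.17	6.07
N011’0c	131.2	0.0	127.3	−136.5	4.96	5.18
N1000c	−162.2	2.1	−177.6	178.5	5.02	5.77
N1010c	−158.2	−5.1	−121.5	135.7	5.67	6.11
N1100c	137.5	−6.4	−175.1	−178.3	5.17	5.05
N1110c	138.9	−3.5	−86.9	132.0	7.52	7.71
N111’0c	140.4	6.9	104.4	−143.9	7.52	7.61
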