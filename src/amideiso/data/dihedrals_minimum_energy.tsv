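compound	psiN_gas	omega_gas	phiC_gas	psiC_gas	psiN_water	omega_water	phiC_water	psiC_water
N0000t	12.8	178.3	175.6	−179.3	15.2	179.2	178.5	−177.4
N0010t	−14.3	177.0	−122.7	141.7	−19.3	178.8	−124.4	142.6
N0100t	−22.8	−179.7	−173.1	178.8	−40.5	−177.9	66.3	−146.4
N0110t	−23.8	169.5	−114.3	141.2	−50.8	171.3	−135.3	152.0
N011’0t	14.3	−178.8	123.0	−140.9	13.4	178.5	127.3	−143.2
N1000t	−15.6	−178.0	−179.1	179.6	12.7	179.5	175.3	−177.3
N1010t	−17.9	176.6	−123.7	141.8	−12.2	178.7	−127.5	141.4
N1100t	140.7	177.5	−175.0	−179.9	134.6	174.6	−163.7	171.2
N1110t	−27.1	172.5	−117.0	140.5	−32.7	174.2	−123.1	141.1
N111’0t	143.0	−169.7	127.2	−145.3	148.2	−173.4	136.1	−147.7
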