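compound	R1	R2	R3
N0000	H	H	H
N0010	H	H	S-t-Bu
N0100	H	S-t-Bu	H
N0110	H	S-t-Bu	S-t-Bu
N011’0	H	S-t-Bu	R-t-Bu
N1000	t-Bu	H	H
N1010	t-Bu	H	S-t-Bu
N1100	t-Bu	S-t-Bu	H
N1110	t-Bu	S-t-Bu	S-t-Bu
N111’0	t-Bu	S-t-Bu	R-t-Bu
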