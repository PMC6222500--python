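attachment	parent	parent_optE	substituted	substituted_optE	Etb_printed
sp3-N	NH3	−35,514.577	tert-Bu-NH2	−134,222.223	−98,707.646
sp3-C	CH4	−25,436.175	tert-Bu-CH3	−124,148.137	−98,711.962
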