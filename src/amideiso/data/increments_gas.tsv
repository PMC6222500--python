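attachment	parent	parent_optE	substituted	substituted_optE	Etb_printed
sp3-N	NH3	−35,508.975	tert-Bu-NH2	−134,218.106	−98,709.131
sp3-C	CH4	−25,437.531	tert-Bu-CH3	−124,149.665	−98,712.134
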