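# gag hybridization probe coordinates (1-based inclusive) on the reference
# elements Ty1-H3 (GenBank M18706) and Ty2-917 (GenBank KT203716).
element	accession	start	end
Ty1-H3	M18706	335	1496
Ty2-917	KT203716	333	1490
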