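# Ty1-H3 neo-AI retromobility frequencies (x 1e-7) across S. paradoxus strains.
# bound=1 marks a detection-limit value ("<frequency").
strain	species	frequency	sd	phenotype	bound
CBS432	S_paradoxus	0.6	0	restrictive	1
N-44	S_paradoxus	0.9	0.8	restrictive	0
YPS138	S_paradoxus	31	7	permissive	0
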