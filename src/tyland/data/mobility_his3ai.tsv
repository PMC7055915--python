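# Ty1-H3 his3-AI retromobility frequencies (x 1e-6) across S. cerevisiae strains,
# with standard deviations and qualitative phenotype.
strain	species	frequency	sd	phenotype	bound
S288c	S_cerevisiae	1.6	0.2	restrictive	0
DBVPG6044	S_cerevisiae	1.0	0.17	restrictive	0
Y12	S_cerevisiae	5.6	0.5	restrictive	0
UWOPS83-787.3	S_cerevisiae	78	5.5	permissive	0
YPS606	S_cerevisiae	157	13	permissive	0
UWOPS05-227.2	S_cerevisiae	458	86	permissive	0
L-1374	S_cerevisiae	635	79	permissive	0
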