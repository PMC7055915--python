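# Ty1-H3 his3-AI mobility (x 1e-6) in natively permissive S. cerevisiae strains
# before and after populating the genome with extra Ty1-H3 copies.
strain	condition	frequency	sd
YPS606	native	164	8.5
YPS606	populated	2.4	0.12
UWOPS05-227.2	native	529	124
UWOPS05-227.2	populated	1	0.25
L-1374	native	461	163
L-1374	populated	3	0.35
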