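# Genomic Ty1 content by strain: structural-class counts and full-length/truncated
# counts partitioned by gag subfamily type (canonical Ty1 vs Ty1').  Truncated
# gag-type counts include only elements spanning the p22 region.
strain	species	phenotype	full_length	truncated	solo_ltr_ty1_ty2	full_canonical_gag	full_ty1prime_gag	trunc_canonical_gag	trunc_ty1prime_gag
S288c	S_cerevisiae	restrictive	38	2	161	35	3	1	1
DBVPG6044	S_cerevisiae	restrictive	19	5	269	19	0	1	1
Y12	S_cerevisiae	restrictive	19	2	158	8	11	0	1
UWOPS83-787.3	S_cerevisiae	permissive	7	3	158	0	7	0	1
YPS606	S_cerevisiae	permissive	3	2	147	0	3	0	1
UWOPS05-227.2	S_cerevisiae	permissive	0	2	185	0	0	0	1
L-1374	S_cerevisiae	permissive	0	1	155	0	0	0	1
CBS432	S_paradoxus	restrictive	8	4	264	8	0	1	0
N-44	S_paradoxus	restrictive	2	3	235	2	0	0	0
YPS138	S_paradoxus	permissive	0	1	232	0	0	0	0
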