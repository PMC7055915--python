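# Functional region annotation on the Ty1-H3 reference frame (5918 bp,
# 1-based inclusive coordinates).  LTR and ORF bounds follow the standard
# published Ty1-H3 organization: 334 bp LTRs, the gag ORF starting inside
# the R region of the 5' LTR, and the overlapping pol ORF read via +1
# frameshifting.  The p22 region defaults to the C-terminal half of gag
# (p22 is encoded there via internal initiation); its two alternative start
# codons, the p18 start, the frameshift heptamer, and the helix/antisense
# interval lists are configurable approximations for synthetic analyses and
# should be overridden with curated coordinates when analysing real elements.
element_length: 5918
ltr5: [1, 334]
gag: [294, 1616]
pol: [1578, 5561]
ltr3: [5585, 5918]
p22_region: [955, 1616]
p22_start_codons: [1038, 1110]
p18_start_codon: 1110
frameshift_heptamer: [1571, 1577]
helix_regions: []
antisense_regions: []
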