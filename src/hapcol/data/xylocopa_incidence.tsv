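# Haplotype x island sample counts for the Galapagos carpenter bee
# (Xylocopa darwini), 12 COII haplotypes in 118 individuals over 9 islands.
# Reconstructed from published per-haplotype distribution statements:
# h3 on six islands (53 samples), h4 on three (25 samples), h11 shared by
# San Cristobal and Espanola, nine single-island haplotypes; island
# haplotype richness 6/4/2/2/2/1/1/1/1. Per-island splits of the remaining
# 40 samples are NOT published; the splits below are synthetic placeholders
# constrained to the published row and richness totals.
haplotype	Isabela	Fernandina	Santiago	Santa Cruz	Genovesa	Floreana	Santa Fe	San Cristobal	Espanola
h3	30	6	4	5	4	4	0	0	0
h4	15	6	0	0	0	0	4	0	0
h5	4	0	0	0	0	0	0	0	0
h6	3	0	0	0	0	0	0	0	0
h7	3	0	0	0	0	0	0	0	0
h8	2	0	0	0	0	0	0	0	0
h9	0	0	0	0	0	3	0	0	0
h10	0	0	0	3	0	0	0	0	0
h11	0	0	0	0	0	0	0	4	6
h12	0	0	0	0	0	0	0	5	0
h13	0	0	0	0	0	0	0	4	0
h14	0	0	0	0	0	0	0	3	0
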