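# Static reference: qualitative colonization patterns reported for animal
# groups across the 12 largest Galapagos islands (paraphrased summaries of
# the source studies; not computed by this package).
group	n_islands_occupied	pattern
Bulimulus land snails	7	diverged early on the southeastern islands, then spread northwest
Buteo hawk	11	arrived recently in the west, expanded rapidly, then became isolated island by island
Chelonoidis tortoises	9	diverged early on central and western islands with repeated later inter-island movement
Galagete moths	12	radiated in step with the emergence order of the major islands and colonized all of them
Galapaganus weevils	9	colonized young Isabela early, deviating from strict volcano-sequence colonization
Microlophus lizards	12	split early into two lineages occupying mainly eastern vs western islands
Mimus mockingbirds	12	colonized northern islands from a southern source (Floreana)
Phyllodactylus geckos	10	ancient colonization predating the current islands, plus an independent mainland arrival in the east
Setophaga warbler	8	arrived on central islands and spread to the rest with moderate inter-island movement
Xylocopa carpenter bee	9	arrived early on a central-western island, reached the east once, then barely moved between islands
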