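# Cross-species colonization summary: published phylogeographic studies of
# island animals and plants (Galapagos, Azores, Canaries), with the number
# of organelle haplotypes, islands occupied, archipelago islands considered
# by each source study, and the inferred inter-island colonization events
# reported there. Olea europaea subsp. guanchica is restricted to the four
# western Canary islands because the eastern islands show hybridization.
species	archipelago	n_individuals	n_islands_occupied	n_archipelago_islands	n_haplotypes	inferred_events
Buteo galapagoensis	Galapagos	122	10	12	7	9
Cistus monspeliensis	Canaries	53	5	7	10	7
Juniperus brevifolia	Azores	71	8	9	16	19
Olea europaea subsp. guanchica	Canaries	98	4	4	11	11
Picconia azorica	Azores	67	7	9	5	10
Setophaga petechia	Galapagos	58	9	12	8	10
Xylocopa darwini	Galapagos	118	9	12	12	10
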