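# Iteron consensus sequences of the ANT_H3 plasmid oriV regions (published
# values), in degenerate (X/Y) notation; unit_bp is the iteron length.
# plasmid	unit_bp	copies	consensus
pA3H1	22	4	CATAAAGCTACGTTTAGCGACC
pA3H2	22	4	CATACCCTTACGTTTAGCGACC
pA3H4	22	4	CATACCACTACGTCTATCGACC
pA3H8	22	4	CATATGACGACAAATTCCTACC
pA3H9	22	4	CT(A/T)(T/G)ATGACTACAAATCCTTAC
pA3H10	22	4	(G/C)ATA(A/G)(A/G)(C/T)ATACGTTTATACACC
pA3H5	21	4	(A/T)(A/T)(A/G)AAGCTAC(A/G)(A/T)(C/T)(A/T)ATCATA(A/G)
pA3H11	20	4	AGAAAAAACAGTAAATGAGC
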