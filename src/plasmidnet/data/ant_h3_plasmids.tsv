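# General features of the Psychrobacter sp. ANT_H3 plasmid set (published values)
# plasmid	accession	size_bp	gc_pct	n_genes	modules
pA3H1	MN657079	3124	36.7	2	REP
pA3H2	MN657082	3336	35.4	2	REP,MOB
pA3H3	MN657083	4211	40.0	3	REP,MOB
pA3H4	MN657084	6059	35.2	5	REP,MOB
pA3H5	MN657085	6238	38.2	4	REP,MOB,DPR
pA3H6	MN657086	6530	41.7	6	REP,MOB
pA3H7	MN657087	6788	41.3	7	REP,MOB
pA3H8	MN657088	8510	41.3	9	REP,MOB,SMR,GCV
pA3H9	MN657089	8574	36.4	8	REP,MOB,RM
pA3H10	MN657080	11826	43.4	14	REP,MOB,RM,MSC
pA3H11	MN657081	13249	40.9	13	REP,MOB,MRS
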