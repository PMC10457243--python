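# REP module coordinates of the ANT_H3 plasmids (published values).
# Coordinates are 1-based inclusive on the circular replicon; start > end
# runs forward through the sequence origin.
# plasmid	accession	start	end	label	non_cutting
pA3H1	MN657079	2670	2399	REP	BamHI,EcoRI,KpnI,NcoI,NheI,PstI,SacI,SalI,SphI,XbaI,XhoI
pA3H2	MN657082	2964	2348	REP	BamHI,EcoRI,EcoRV,KpnI,NcoI,NheI,PstI,SacI,SalI,SphI,XbaI,XhoI
pA3H3	MN657083	3957	1854	REP	BamHI,EcoRI,KpnI,NcoI,NheI,SacI,SalI,SphI,XbaI,XhoI
pA3H4	MN657084	5628	1728	REP	BamHI,EcoRI,EcoRV,KpnI,NcoI,SacI,SalI,XbaI,XhoI
pA3H5	MN657085	6087	1326	REP	BamHI,EcoRI,EcoRV,HindIII,KpnI,NcoI,NheI,SacI,SalI,SphI,XbaI,XhoI
pA3H6	MN657086	6396	1430	REP	BamHI,EcoRI,EcoRV,KpnI,NcoI,NheI,PstI,SacI,SalI,XbaI,XhoI
pA3H7	MN657087	6363	1532	REP	BamHI,EcoRI,EcoRV,KpnI,NcoI,PstI,SacI,SalI,SphI,XbaI,XhoI
pA3H8	MN657088	8303	2062	REP	BamHI,EcoRI,KpnI,NcoI,PstI,SacI,SalI,SphI,XhoI
pA3H9	MN657089	8354	1571	REP	BamHI,EcoRI,HindIII,KpnI,NcoI,NheI,PstI,SacI,SalI,XbaI,XhoI
pA3H10	MN657080	11689	1350	REP	BamHI,EcoRV,KpnI,NcoI,NheI,SacI,SalI,XbaI,XhoI
pA3H11	MN657081	13052	1491	REP	BamHI,EcoRI,EcoRV,KpnI,NcoI,NheI,SacI,SalI,SphI,XbaI,XhoI
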