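chrom	txStart	txEnd	name	foldchange	regulation
chr21	40400925	40401053	AF064858.10	1135.5	hypermethylated
chr2	43256052	43256660	LOC102723854	944	hypermethylated
chr10	13246218	13246526	MCM10	650.5	hypermethylated
chr8	145580221	145580373	FBXL6	529.3	hypermethylated
chr1	31989461	31989846	LINC01226	503.3	hypermethylated
chr12	114204879	114204900	LINC01234	468.7	hypermethylated
chr11	61521500	61521917	DKFZP434K028	460	hypermethylated
chr15	28594381	28594740	RP11-483E23.2	451.3	hypermethylated
chr3	101679229	101679575	RP11-221J22.2	330.1	hypermethylated
chr3	186454327	186454439	RP11-573D15.8	295.4	hypermethylated
chr14	94406121	94406460	ASB2	138.3	hypomethylated
chr21	44188481	44188522	PDE9A	99.7	hypomethylated
chr11	68781258	68781260	MRGPRF-AS1	77.5	hypomethylated
chr16	1277701	1277790	TPSB2	72.8	hypomethylated
chr16	10273781	10274120	GRIN2A	52.9	hypomethylated
chr2	98967381	98967603	AC092675.4	50.9	hypomethylated
chr4	144465241	144465509	SMARCA5	50.2	hypomethylated
chr14	103606011	103606120	RP11-736N17.4	46.1	hypomethylated
chr15	57982841	57983080	GCOM1	39.2	hypomethylated
chr10	7659681	7659940	ITIH5	32.9	hypomethylated
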