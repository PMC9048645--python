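position	strand	circ_id	genomic_length	spliced_length	gene_symbol	rbps
chr9:22056250-22064017	+	hsa_circ_0086590	7767	981	CDKN2B-AS	EIF4A3
chr9:22046749-22097363	+	hsa_circ_0008796	50614	1719	CDKN2B-AS	EIF4A3, U2AF65
chr9:22046315-22097363	+	hsa_circ_0004297	51048	1852	CDKN2B-AS	EIF4A3
chr9:21994789-22066352	+	hsa_circ_0086587	71563	2448	CDKN2B-AS	EIF4A3, FUS, PTB
chr9:22046749-22112394	+	hsa_circ_0004735	65645	1795	CDKN2B-AS	AUF1, EIF4A3, U2AF65, TIAL1
chr9:22046749-22065756	+	hsa_circ_0086589	19007	1350	CDKN2B-AS	EIF4A3, U2AF65, FUS
chr9:22046749-22056386	+	hsa_circ_0008574	9637	409	CDKN2B-AS	EIF4A3, U2AF65, PTB
chr9:22046315-22065756	+	hsa_circ_0086588	19441	1483	CDKN2B-AS	EIF4A3, FUS
chr9:22056250-22065756	+	hsa_circ_0086591	9506	1077	CDKN2B-AS	EIF4A3, FUS
chr9:22043037-22097363	+	hsa_circ_0003306	54326	5130	CDKN2B-AS	EIF4A3, PTB
chr9:22046749-22064017	+	hsa_circ_0005118	17268	1254	CDKN2B-AS	U2AF65, EIF4A3
chr9:22058357-22066352	+	hsa_circ_0086592	7995	1060	CDKN2B-AS	EIF4A3, FUS, PTB
chr9:22046749-22066352	+	hsa_circ_0004226	19603	1469	CDKN2B-AS	EIF4A3, FUS, PTB, U2AF65
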