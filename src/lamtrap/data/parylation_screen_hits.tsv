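# Final filtered hit table of the PARylation gene-trap screen (transcribed).
# 20 insertion sites in 17 genes; NPM1, CTIF and CCDC171 were each recovered
# at two independent sites.  Positions are 1-based GRCh37 coordinates.
Chr	Strand orientation	Insertion site (genomic position)	Median_read_sample	Nr Insertion sites	Gene	Gene ID	Truncation (N-terminal AA)	Protein length (AA)
5	+	170827447	502	2	NPM1	ENSG00000181163	195	259
5	+	170823418	321	2	NPM1	ENSG00000181163	174	259
18	+	46304668	1131	2	CTIF	ENSG00000134030	459	600
18	+	46366092	777	2	CTIF	ENSG00000134030	551	600
9	+	15888921	471	2	CCDC171	ENSG00000164989	1200	1326
9	+	15887412	361	2	CCDC171	ENSG00000164989	1200	1326
1	+	95306653	972	1	SLC44A3	ENSG00000143036	253	653
8	-	119229899	612	1	SAMD12	ENSG00000177570	155	161
6	+	25600895	572	1	LRRC16A	ENSG00000079691	1039	1371
5	-	76998018	420	1	TBCA	ENSG00000171530	55	108
19	+	39122699	377.5	1	EIF3K	ENSG00000178982	119	218
3	-	30786048	376	1	GADL1	ENSG00000144644	464	521
19	-	40368616	339.5	1	FCGBP	ENSG00000090920	4157	5405
9	+	130443026	313.5	1	STXBP1	ENSG00000136854	515	594
3	+	142745673	166	1	U2SURP	ENSG00000163714	426	1029
19	+	10797868	144	1	ILF3	ENSG00000129351	690	702
2	-	45729067	80	1	SRBD1	ENSG00000068784	624	995
3	+	29904702	43.5	1	RBMS3	ENSG00000144642	212	433
3	+	155641886	38	1	GMPS	ENSG00000163655	478	693
4	+	71665115	22	1	RUFY3	ENSG00000018189	520	620
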