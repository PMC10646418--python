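transcript_id	gene_id	n_isoforms	locus_hg19	strand	locus_class	fpkm_islet	fpkm_pbs_graft	fpkm_alt_graft	noncode_top_tissue	noncode_top_fpkm	nearest_genes
lnc-SCYL1-1:22	lnc-SCYL1-1	23	chr11:65266530-65273915	+	Intergenic	321.526	224.598	820.17	Heart	100.17	SCYL1:-22325,FRMD8:+116153
lnc-POLG2-1:1	lnc-POLG2-1	6	chr17:62499838-62500407	-	Exonic	152.589	34.7796	7.93116	Thyroid	74.41	POLG2:-6969,DDX5:+2516
lnc-CTRB1-1:1	lnc-CTRB1-1	5	chr16:75259972-75262093	+	Intergenic	60.2895	17.1439	1.48629	Kidney	0.069	CTRB1:+8135,BCAR1:+38872
lnc-SRPK1-1:1	lnc-SRPK1-1	1	chr6:35762887-35765057	-	Exonic	751.402	667.018	0.00328	Testes	4.366	CLPS:+1116,CLPSL1:+15178
lnc-GTF3C5-1:1	lnc-GTF3C5-1	1	chr9:135945998-135946529	+	Exonic	3967.02	583.643	13.8299	Testes	22.859	CEL:+8899,RALGDS:+50299
lnc-PPY-1:1	lnc-PPY-1	2	chr17:42018172-42018882	-	Exonic	202.857	295.959	75.9507	Colon	0.119	PPY:+1115,FAM215A:+23951
lnc-CTRB1-1:5	lnc-CTRB1-1	5	chr16:75260884-75262093	+	Intergenic	59.2148	8.53556	0.20497	Hela	0.16	CTRB1:+8591,BCAR1:+38416
lnc-CTRB1-1:4	lnc-CTRB1-1	5	chr16:75260415-75261204	+	Intergenic	69.6761	17.1526	0.95125	Testes	0.324	CTRB1:+7912,BCAR1:+39095
lnc-CPA5-1:1	lnc-CPA5-1	1	chr7:130023540-130024902	+	Exonic	1654.05	276.387	16.1761	Placenta	0.466	CPA1:+4009,CEP41:+56857
lnc-BCAR1-2:1	lnc-BCAR1-2	1	chr16:75238035-75241057	-	Exonic	166.438	48.2731	7.61982	Brain	0.272	CTRB2:+1537,ZFP1:+57066
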