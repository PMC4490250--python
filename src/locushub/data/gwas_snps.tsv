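rsid	chrom	pos	gene	study
rs174535	11	61551356	MYRF/FADS1	T2D-meta-2010
rs7202844	16	75247391	CTRB1/BCAR1	DIAGRAM
rs10160034	10	91352850	PANK1	T2D-reseq-2014
rs1801214	4	6303022	WFS1	DIAGRAM
rs16860235	3	185512361	IGF2BP2	DIAGRAM
rs1169288	12	120978847	HNF1A	T2D-meta-2010
rs2001844	8	126478745	NA	T2D-meta-2010
rs6909	19	19619542	GATAD2A	T2D-reseq-2014
rs7798124	7	15055616	NA	DIAGRAM
rs7168849	15	90346227	ANPEP	DIAGRAM
rs7111	15	90373873	AP3S2	DIAGRAM
rs11755566	6	38116669	ZFAND3	DIAGRAM
rs3741530	12	123469647	ABCB9/PITPNM2	T2D-trans-ethnic
rs703977	10	944230	ZMIZ1	DIAGRAM
rs11683087	2	227586606	IRS1	T2D-meta-2012
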