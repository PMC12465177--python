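allele_id	label	case_ids	gene	hgvs_g	hgvs_c	hgvs_p	zygosity	kind	classification	codon_consistent	notes
COL2A1_bt_del	COL2A1 Holstein 12-bp deletion	1	COL2A1	Chr5:g.32312706_32312718del	c.4432_4443del	p.(Gly1478_Ile1481del)	heterozygous	inframe_deletion	pathogenic	1	printed g. span is 13 bp, one longer than the 12-bp c. span; the c. description is the tested value
COL2A1_oa_G970S	COL2A1 ovine Gly970Ser	2,3,4,5,6,7	COL2A1	Chr3:g.138610131G>A	c.2908G>A	p.Gly970Ser	heterozygous	missense	pathogenic	1
PPIB_intronic	PPIB intron 3	8	PPIB	Chr10:g.45822912G>C	c.320-443G>C		homozygous	intronic	uncertain	1	intronic offset notation; excluded from codon arithmetic
COL1A2_G386R	COL1A2 Gly386Arg	9,10	COL1A2	Chr4:g.11792118G>A	c.1156G>A	p.Gly386Arg	heterozygous	missense	pathogenic	1
COL1A1_G397S	COL1A1 ovine Gly397Ser	11,12,13	COL1A1	Chr11:g.36197409G>A	c.1189G>A	p.Gly397Ser	heterozygous	missense	pathogenic	1
DCAF12L2_S111X	LOC112445140 Ser111*	14	LOC112445140	ChrX:g.10872688G>T	c.332C>A	p.Ser111*	heterozygous	nonsense	pathogenic	1	heterozygous female X-linked case
SLC40A1_I108N	SLC40A1 Ile108Asn	15	SLC40A1	Chr2:g.6785954T>A	c.323T>A	p.Ile108Asn	heterozygous	missense	pathogenic	1
PTPN9_A276T	PTPN9 Ala276Thr	17	PTPN9	Chr21:g.33356490G>A	c.826G>A	p.Ala276Thr	heterozygous	missense	uncertain	1
PRDM10_P289L	PRDM10 Pro289Leu	18,19	PRDM10	Chr29:g.36138136G>A	c.866C>T	p.Pro289Leu	heterozygous	missense	pathogenic	1
PDGFRA_I562T	PDGFRA Ile562Thr	21	PDGFRA	Chr6:g.69749162T>C	c.1685T>C	p.Ile562Thr	heterozygous	missense	pathogenic	1
ABCC8_M959V	ABCC8 Met959Val	22	ABCC8	Chr15:g.35095352A>G	c.2875A>G	p.Met959Val	heterozygous	missense	likely_pathogenic	1
LRP4_allele1	LRP4 Holstein allele 1	26,27	LRP4	Chr15:g.76800972CdelinsAT	c.4863_4864delinsAT	p.Asn1621_Gly1622delinsLysCys	compound-partner	delins	pathogenic	1	known causal indel, shared by cases 26 and 27
LRP4_allele2	LRP4 Holstein allele 2	26	LRP4	Chr15:g.76800896G>A	c.4940C>T	p.Pro1647Leu	compound-partner	missense	pathogenic	1	single-copy carriers in 403 control genomes
LRP4_allele3	LRP4 Holstein allele 3	27	LRP4	Chr15:g.76819481G>A	c.1480C>T	p.Arg494Cys	compound-partner	missense	pathogenic	1	single-copy carriers in 697 control genomes
KMT2C_P2011T	KMT2C Pro2011Thr	28	KMT2C	Chr4:g.114640130G>T	c.6031C>A	p.Pro2011Thr	homozygous	missense	uncertain	1
CD4_P20L	CD4 Pro20Leu	29	CD4	Chr5:g.103647362G>A	c.59C>T	p.Pro20Leu	homozygous	missense	uncertain	1
CCT3_Y303H	CCT3 Tyr303His	32	CCT3	Chr3:g.14497551T>C	c.907T>C	p.Tyr303His	heterozygous	missense	likely_pathogenic	1
ITGAE_I329T	ITGAE Ile329Thr	33	ITGAE	Chr19:g.24423519A>G	c.986T>C	p.Ile329Thr	homozygous	missense	likely_pathogenic	1
CNTNAP1_allele1	CNTNAP1 allele 1	34	CNTNAP1	Chr19:g.42747176G>A	c.1495G>A	p.Ala734Thr	compound-partner	missense	likely_pathogenic	0	printed codon 734 is inconsistent with ceil(1495/3)=499; excluded from codon checks
CNTNAP1_allele2	CNTNAP1 allele 2	34	CNTNAP1	Chr19:g.42748559G>A	c.2531-52G>A		compound-partner	intronic	likely_pathogenic	1	intronic offset notation; excluded from codon arithmetic
NFE2L1_L178del	NFE2L1 Leu178del	35	NFE2L1	Chr19:g.38426902AAGG>A	c.531_533delCCT	p.Leu178del	heterozygous	inframe_deletion	likely_pathogenic	1	3-bp deletion spanning codons 177-178 as printed
IL16_N542D	IL16 Asn542Asp	36	IL16	Chr21:g.27078178A>G	c.1624A>G	p.Asn542Asp	heterozygous	missense	likely_pathogenic	1
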