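position	ref	alt	length	type	gene	context	aa_change	literature
34491252	C	G	1	snp	oaz1	exon
34491407	A	C	1	snp	oaz1	exon	Leu->Gly
34491477	C	T	1	snp	oaz1	intron
34491574	T	C	1	snp	oaz1	exon	Lys->Glu	Caceres et al., 2019
34492052	A	G	1	snp	oaz1	intron
34492058	T	C	1	snp	oaz1	intron
34492381	A	G	1	snp	oaz1	intron
34493190	G	C	1	snp	oaz1	intron
34493277	A	G	1	snp	oaz1	intron
34498917	A	G	1	snp	LOC100707471	intron
34499201	CTAT	TTAC	4	complex	amh	3'UTR
34499475	A	G	1	snp	amh	3'UTR
34499597	C	T	1	snp	amh	exon 7
34499645	A	C	1	snp	amh	exon 7
34499675	A	G	1	snp	amh	exon 7
34499706	G	C	1	snp	amh	exon 7	Thr->Ser
34499810	A	G	1	snp	amh	exon 7
34499839	C	T	1	snp	amh	exon 7	Ala->Thr
34499987	C	T	1	snp	amh	intron
34499994	A	C	1	snp	amh	intron
34500307	C	T	1	snp	amh	intron
34500348	T	C	1	snp	amh	intron
34500364	G	C	1	snp	amh	intron
34500464	G	A	1	snp	amh	intron
34500668	C	A	1	snp	amh	intron
34500750	G	A	1	snp	amh	intron
34500773	C	T	1	snp	amh	exon 6	Glu->Lys
34501082	T	C	1	snp	amh	exon 6	Thr->Ala	Caceres et al., 2019
34501555	C	T	1	snp	amh	intron
34502034	T	C	1	snp	amh	exon 3	Asn->Ser	Caceres et al., 2019; Li et al., 2015
34502075	T	A	1	snp	amh	exon 3		Li et al., 2015
34502169	ATG	AGTG	1	insertion	amh	intron
34502196	G	A	1	snp	amh	intron
34502353	A	C	1	snp	amh	exon 2	Asp->Glu	Li et al., 2015
34502501	T	C	1	snp	amh	intron
34502686	T	C	1	snp	amh	5'UTR
34502748	T	C	1	snp	amh	5'UTR		Caceres et al., 2019
34502756	C	T	1	snp	amh	5'UTR		Caceres et al., 2019
34502954	G	A	1	snp		non-coding
34509735	T	C	1	snp	dot1l	3'UTR
34509898	T	A	1	snp	dot1l	3'UTR
34509976	T	C	1	snp	dot1l	3'UTR
34510100	G	T	1	snp	dot1l	3'UTR
34510131	C	G	1	snp	dot1l	3'UTR
34510239	TTTAACT	TT	5	deletion	dot1l	3'UTR
34510250	A	C	1	snp	dot1l	3'UTR
34510260	A	G	1	snp	dot1l	3'UTR
34510309	A	G	1	snp	dot1l	3'UTR
34510392	A	G	1	snp	dot1l	3'UTR
34510428	GACA	GA	2	deletion	dot1l	3'UTR
34510495	T	G	1	snp	dot1l	3'UTR
34510529	C	T	1	snp	dot1l	3'UTR		Caceres et al., 2019
34510747	G	C	1	snp	dot1l	3'UTR
34510768	TGTGTGCG	TG	6	deletion	dot1l	3'UTR
34510842	CTTTTTTTTTTTTTTC	CTTTTTTTTTC,CTTTTTTTTC	5	deletion	dot1l	3'UTR
34511324	TAAATG	TAATG	1	deletion	dot1l	3'UTR
34511937	T	C	1	snp	dot1l	exon
34511950	A	T	1	snp	dot1l	exon	Leu->His
34511973	T	C	1	snp	dot1l	exon
34512585	ACAA	GCAG	4	complex	dot1l	intron
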