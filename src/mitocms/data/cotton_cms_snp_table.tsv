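gene	position	nt_ref	nt_alt	aa_ref	aa_alt	reported_effect	reported_snp_class
cox1	495890	C	A	Ile	Ile	S	transversion
cox1	496358	C	A	Ile	Ile	S	transversion
cox3	494152	C	A	Leu	Ile	N	transversion
nad7	583680	A	C	Ile	Ile	S	transversion
atp4	307826	C	T	Phe	Phe	S	transition
atp8	205705	C	A	Ser	Arg	N	transversion
sdh3	317242	A	C	Leu	Phe	N	transversion
matR	16075	C	A	Cys	Lys	N	transversion
rps4	426548	A	C	Lys	Cys	N	transversion
rpl2	458973	T	G	Phe	Leu	N	transversion
rpl2	459220	A	C	Ile	Leu	N	transversion
rpl5	457988	A	C	Lys	Cys	N	transversion
rpl10	171493	G	A	Gln	Lys	N	transition
rpl16	399033	A	C	Val	Val	S	transversion
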