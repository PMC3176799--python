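replicon_id	gene	start	end	strand	replicon_length	gc_percent
Rcapsulatus	gyrA	150001	150900	+	3871900	66
Rcapsulatus	recA	400001	400900	+	3871900	66
Rcapsulatus	dnaK	650001	650900	+	3871900	66
Rcapsulatus	hemA	1000001	1000814	-	3871900	66
Rcapsulatus	puhE	1000997	1001809	-	3871900	66
Rcapsulatus	ascF	1001992	1002723	-	3871900	66
Rcapsulatus	hyp	1002906	1003830	-	3871900	66
Rcapsulatus	puhC	1004013	1004898	-	3871900	66
Rcapsulatus	puhB	1005080	1005864	-	3871900	66
Rcapsulatus	puhA	1006046	1006996	-	3871900	66
Rcapsulatus	lhaA	1007178	1007909	-	3871900	66
Rcapsulatus	bchM	1008091	1008900	-	3871900	66
Rcapsulatus	bchL	1009082	1009822	-	3871900	66
Rcapsulatus	bchH	1010004	1010883	-	3871900	66
Rcapsulatus	bchB	1011065	1011923	-	3871900	66
Rcapsulatus	bchN	1012105	1013020	-	3871900	66
Rcapsulatus	bchF	1013202	1014069	-	3871900	66
Rcapsulatus	crtJ	1014251	1015087	-	3871900	66
Rcapsulatus	ppaA	1015269	1016361	-	3871900	66
Rcapsulatus	ppsR	1016543	1017415	-	3871900	66
Rcapsulatus	bchG	1017597	1018691	-	3871900	66
Rcapsulatus	bchP	1018873	1019605	-	3871900	66
Rcapsulatus	bchO	1019787	1020693	-	3871900	66
Rcapsulatus	bchD	1020875	1021690	-	3871900	66
Rcapsulatus	bchI	1021872	1022583	-	3871900	66
Rcapsulatus	bchE	1022765	1023729	+	3871900	66
Rcapsulatus	bchJ	1023911	1024757	+	3871900	66
Rcapsulatus	crtA	1024939	1026007	+	3871900	66
Rcapsulatus	crtI	1026189	1027084	+	3871900	66
Rcapsulatus	crtB	1027266	1028242	+	3871900	66
Rcapsulatus	crtK	1028424	1029392	+	3871900	66
Rcapsulatus	hyp	1029574	1030614	+	3871900	66
Rcapsulatus	crtC	1030796	1031495	+	3871900	66
Rcapsulatus	crtD	1031677	1032733	+	3871900	66
Rcapsulatus	crtE	1032915	1033953	+	3871900	66
Rcapsulatus	crtF	1034135	1035038	+	3871900	66
Rcapsulatus	bchC	1035220	1036018	+	3871900	66
Rcapsulatus	bchX	1036200	1037198	+	3871900	66
Rcapsulatus	bchY	1037380	1038140	+	3871900	66
Rcapsulatus	bchZ	1038322	1039125	+	3871900	66
Rcapsulatus	pufQ	1039307	1040209	+	3871900	66
Rcapsulatus	pufB	1040391	1041472	+	3871900	66
Rcapsulatus	pufA	1041654	1042595	+	3871900	66
Rcapsulatus	pufL	1042777	1043842	+	3871900	66
Rcapsulatus	pufM	1044024	1044727	+	3871900	66
Rcapsulatus	pufX	1044909	1046000	+	3871900	66
Rcapsulatus	rpoB	2700001	2700900	+	3871900	66
Rcapsulatus	ftsZ	2900001	2900900	+	3871900	66
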