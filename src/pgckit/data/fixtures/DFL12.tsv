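replicon_id	gene	start	end	strand	replicon_length	gc_percent
DFL12	gyrA	150001	150900	+	4417800	65
DFL12	recA	400001	400900	+	4417800	65
DFL12	dnaK	650001	650900	+	4417800	65
DFL12	crtA	1000001	1000819	+	4417800	65
DFL12	hyp	1001096	1001870	+	4417800	65
DFL12	crtI	1002147	1003079	+	4417800	65
DFL12	crtB	1003356	1004157	+	4417800	65
DFL12	crtK	1004434	1005246	+	4417800	65
DFL12	crtC	1005523	1006420	+	4417800	65
DFL12	crtD	1006697	1007743	+	4417800	65
DFL12	crtE	1008020	1008983	+	4417800	65
DFL12	crtF	1009260	1010279	+	4417800	65
DFL12	bchC	1010556	1011556	+	4417800	65
DFL12	bchX	1011833	1012719	+	4417800	65
DFL12	bchY	1012996	1013984	+	4417800	65
DFL12	bchZ	1014261	1015044	+	4417800	65
DFL12	pufQ	1015321	1016156	+	4417800	65
DFL12	pufB	1016433	1017385	+	4417800	65
DFL12	pufA	1017662	1018600	+	4417800	65
DFL12	pufL	1018877	1019770	+	4417800	65
DFL12	pufM	1020047	1021135	+	4417800	65
DFL12	pufC	1021412	1022212	+	4417800	65
DFL12	dxps	1022489	1023471	+	4417800	65
DFL12	bchI	1023748	1024816	+	4417800	65
DFL12	bchD	1025093	1025879	+	4417800	65
DFL12	bchO	1026156	1027011	+	4417800	65
DFL12	bchP	1027288	1028043	+	4417800	65
DFL12	bchG	1028320	1029232	+	4417800	65
DFL12	ppsR	1029509	1030491	+	4417800	65
DFL12	ppaA	1030768	1031545	+	4417800	65
DFL12	bchF	1031822	1032867	+	4417800	65
DFL12	bchN	1033144	1034226	+	4417800	65
DFL12	bchB	1034503	1035358	+	4417800	65
DFL12	bchH	1035635	1036334	+	4417800	65
DFL12	bchL	1036611	1037356	+	4417800	65
DFL12	bchM	1037633	1038570	+	4417800	65
DFL12	lhaA	1038847	1039760	+	4417800	65
DFL12	puhA	1040037	1041110	+	4417800	65
DFL12	puhB	1041387	1042297	+	4417800	65
DFL12	puhC	1042574	1043452	+	4417800	65
DFL12	hyp	1043729	1044760	+	4417800	65
DFL12	ascF	1045036	1045973	+	4417800	65
DFL12	puhE	1046249	1046991	+	4417800	65
DFL12	hemA	1047267	1048100	+	4417800	65
DFL12	rpoB	2700001	2700900	+	4417800	65
DFL12	ftsZ	2900001	2900900	+	4417800	65
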