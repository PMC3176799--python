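replicon_id	gene	start	end	strand	replicon_length	gc_percent
JL354	gyrA	150001	150900	+	3273300	65
JL354	recA	400001	400900	+	3273300	65
JL354	dnaK	650001	650900	+	3273300	65
JL354	crtC	1000001	1000721	+	3273300	65
JL354	crtF	1001091	1001818	+	3273300	65
JL354	bchC	1002188	1003174	+	3273300	65
JL354	bchX	1003544	1004570	+	3273300	65
JL354	bchY	1004940	1005900	+	3273300	65
JL354	bchZ	1006270	1007226	+	3273300	65
JL354	pufB	1007596	1008328	+	3273300	65
JL354	pufA	1008698	1009475	+	3273300	65
JL354	pufL	1009845	1010714	+	3273300	65
JL354	pufM	1011084	1012019	+	3273300	65
JL354	bchI	1012389	1013125	+	3273300	65
JL354	bchD	1013495	1014553	+	3273300	65
JL354	bchO	1014923	1015966	+	3273300	65
JL354	bchP	1016336	1017215	+	3273300	65
JL354	bchG	1017585	1018562	+	3273300	65
JL354	ppsR	1018932	1019710	+	3273300	65
JL354	ppaA	1020080	1020893	+	3273300	65
JL354	bchF	1021263	1022105	+	3273300	65
JL354	bchN	1022475	1023250	+	3273300	65
JL354	bchB	1023620	1024336	+	3273300	65
JL354	bchH	1024705	1025440	+	3273300	65
JL354	bchL	1025809	1026835	+	3273300	65
JL354	bchM	1027204	1028258	+	3273300	65
JL354	lhaA	1028627	1029520	+	3273300	65
JL354	puhA	1029889	1030912	+	3273300	65
JL354	puhB	1031281	1032304	+	3273300	65
JL354	puhC	1032673	1033706	+	3273300	65
JL354	hyp	1034075	1034998	+	3273300	65
JL354	ascF	1035367	1036111	+	3273300	65
JL354	puhE	1036480	1037569	+	3273300	65
JL354	hemA	1037938	1038700	+	3273300	65
JL354	crtI	2000001	2000900	+	3273300	65
JL354	crtB	2025001	2025900	-	3273300	65
JL354	crtE	2050001	2050900	+	3273300	65
JL354	crtY	2075001	2075900	-	3273300	65
JL354	crtZ	2100001	2100900	+	3273300	65
JL354	crtW	2125001	2125900	-	3273300	65
JL354	rpoB	2700001	2700900	+	3273300	65
JL354	ftsZ	2900001	2900900	+	3273300	65
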