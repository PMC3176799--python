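replicon_id	gene	start	end	strand	replicon_length	gc_percent
KT71	gyrA	150001	150900	+	4328100	58
KT71	recA	400001	400900	+	4328100	58
KT71	dnaK	650001	650900	+	4328100	58
KT71	bluf	1000001	1000842	+	4328100	58
KT71	ascF	1001205	1001971	+	4328100	58
KT71	bchI	1002334	1003226	+	4328100	58
KT71	bchD	1003589	1004614	+	4328100	58
KT71	bchO	1004977	1005897	+	4328100	58
KT71	bchP	1006260	1007046	+	4328100	58
KT71	bchG	1007409	1008144	+	4328100	58
KT71	crtJ	1008507	1009600	+	4328100	58
KT71	bchF	1009963	1010764	+	4328100	58
KT71	bchN	1011127	1012220	+	4328100	58
KT71	bchB	1012583	1013364	+	4328100	58
KT71	bchH	1013727	1014764	+	4328100	58
KT71	bchL	1015127	1015967	+	4328100	58
KT71	bchM	1016330	1017188	+	4328100	58
KT71	lhaA	1017551	1018497	+	4328100	58
KT71	puhA	1018860	1019568	+	4328100	58
KT71	puhB	1019931	1021021	+	4328100	58
KT71	puhC	1021384	1022191	+	4328100	58
KT71	puhE	1022554	1023423	+	4328100	58
KT71	hemN	1023786	1024634	+	4328100	58
KT71	pufA	1024997	1026029	-	4328100	58
KT71	pufB	1026391	1027165	-	4328100	58
KT71	pufC	1027527	1028550	-	4328100	58
KT71	pufM	1028912	1029691	-	4328100	58
KT71	pufL	1030053	1031109	-	4328100	58
KT71	bchZ	1031471	1032338	-	4328100	58
KT71	bchY	1032700	1033426	-	4328100	58
KT71	bchX	1033788	1034826	-	4328100	58
KT71	bchC	1035188	1036166	-	4328100	58
KT71	crtF	1036528	1037408	-	4328100	58
KT71	crtE	1037770	1038600	-	4328100	58
KT71	crtC	1038962	1040015	-	4328100	58
KT71	crtB	1040377	1041137	-	4328100	58
KT71	crtI	1041499	1042363	-	4328100	58
KT71	bchJ	1042725	1043510	-	4328100	58
KT71	bchE	1043872	1044700	-	4328100	58
KT71	crtD	2000001	2000900	+	4328100	58
KT71	rpoB	2700001	2700900	+	4328100	58
KT71	ftsZ	2900001	2900900	+	4328100	58
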