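replicon_id	gene	start	end	strand	replicon_length	gc_percent
Rsphaeroides	gyrA	150001	150900	+	4602000	69
Rsphaeroides	recA	400001	400900	+	4602000	69
Rsphaeroides	dnaK	650001	650900	+	4602000	69
Rsphaeroides	hemA	1000001	1000977	-	4602000	69
Rsphaeroides	puhE	1001163	1001900	-	4602000	69
Rsphaeroides	ascF	1002086	1003054	-	4602000	69
Rsphaeroides	hyp	1003240	1004153	-	4602000	69
Rsphaeroides	puhC	1004339	1005046	-	4602000	69
Rsphaeroides	puhB	1005232	1006298	-	4602000	69
Rsphaeroides	puhA	1006484	1007230	-	4602000	69
Rsphaeroides	lhaA	1007416	1008508	-	4602000	69
Rsphaeroides	bchM	1008694	1009728	-	4602000	69
Rsphaeroides	bchL	1009914	1010953	-	4602000	69
Rsphaeroides	bchH	1011139	1012013	-	4602000	69
Rsphaeroides	bchB	1012199	1013197	-	4602000	69
Rsphaeroides	bchN	1013383	1014436	-	4602000	69
Rsphaeroides	bchF	1014622	1015485	-	4602000	69
Rsphaeroides	ppaA	1015671	1016561	-	4602000	69
Rsphaeroides	ppsR	1016747	1017672	-	4602000	69
Rsphaeroides	bchG	1017858	1018768	-	4602000	69
Rsphaeroides	bchP	1018954	1019686	-	4602000	69
Rsphaeroides	bchO	1019872	1020599	-	4602000	69
Rsphaeroides	bchD	1020785	1021743	-	4602000	69
Rsphaeroides	bchI	1021929	1022671	-	4602000	69
Rsphaeroides	bchE	1022857	1023660	+	4602000	69
Rsphaeroides	bchJ	1023846	1024709	+	4602000	69
Rsphaeroides	crtA	1024895	1025944	+	4602000	69
Rsphaeroides	crtI	1026130	1027049	+	4602000	69
Rsphaeroides	crtB	1027235	1027950	+	4602000	69
Rsphaeroides	crtK	1028136	1029041	+	4602000	69
Rsphaeroides	hyp	1029227	1030323	+	4602000	69
Rsphaeroides	crtC	1030509	1031228	+	4602000	69
Rsphaeroides	crtD	1031414	1032390	+	4602000	69
Rsphaeroides	crtE	1032576	1033506	+	4602000	69
Rsphaeroides	crtF	1033692	1034730	+	4602000	69
Rsphaeroides	bchC	1034916	1035644	+	4602000	69
Rsphaeroides	bchX	1035830	1036813	+	4602000	69
Rsphaeroides	bchY	1036999	1037920	+	4602000	69
Rsphaeroides	bchZ	1038106	1038832	+	4602000	69
Rsphaeroides	pufQ	1039018	1039881	+	4602000	69
Rsphaeroides	pufB	1040067	1040811	+	4602000	69
Rsphaeroides	pufA	1040997	1041789	+	4602000	69
Rsphaeroides	pufL	1041975	1042741	+	4602000	69
Rsphaeroides	pufM	1042927	1043727	+	4602000	69
Rsphaeroides	pufX	1043912	1045000	+	4602000	69
Rsphaeroides	rpoB	2700001	2700900	+	4602000	69
Rsphaeroides	ftsZ	2900001	2900900	+	4602000	69
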