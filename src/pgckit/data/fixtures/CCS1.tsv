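replicon_id	gene	start	end	strand	replicon_length	gc_percent
CCS1	gyrA	150001	150900	+	4404000	62
CCS1	recA	400001	400900	+	4404000	62
CCS1	dnaK	650001	650900	+	4404000	62
CCS1	crtC	1000001	1000991	+	4404000	62
CCS1	crtD	1001284	1001983	+	4404000	62
CCS1	crtE	1002276	1003022	+	4404000	62
CCS1	crtA	1003315	1004066	+	4404000	62
CCS1	crtI	1004359	1005135	+	4404000	62
CCS1	crtB	1005428	1006182	+	4404000	62
CCS1	crtF	1006475	1007478	+	4404000	62
CCS1	bchC	1007771	1008622	+	4404000	62
CCS1	bchX	1008915	1009753	+	4404000	62
CCS1	bchY	1010046	1010993	+	4404000	62
CCS1	bchZ	1011286	1012352	+	4404000	62
CCS1	pufQ	1012645	1013679	+	4404000	62
CCS1	pufB	1013972	1014853	+	4404000	62
CCS1	pufA	1015146	1015895	+	4404000	62
CCS1	pufL	1016188	1017215	+	4404000	62
CCS1	pufM	1017508	1018431	+	4404000	62
CCS1	pufC	1018724	1019551	+	4404000	62
CCS1	dxps	1019844	1020652	+	4404000	62
CCS1	bchI	1020945	1021813	+	4404000	62
CCS1	bchD	1022106	1023135	+	4404000	62
CCS1	bchO	1023428	1024321	+	4404000	62
CCS1	bchP	1024613	1025569	+	4404000	62
CCS1	bchG	1025861	1026851	+	4404000	62
CCS1	ppsR	1027143	1027928	+	4404000	62
CCS1	ppaA	1028220	1029106	+	4404000	62
CCS1	bchF	1029398	1030113	+	4404000	62
CCS1	bchN	1030405	1031300	+	4404000	62
CCS1	bchB	1031592	1032488	+	4404000	62
CCS1	bchH	1032780	1033508	+	4404000	62
CCS1	bchL	1033800	1034629	+	4404000	62
CCS1	bchM	1034921	1035743	+	4404000	62
CCS1	lhaA	1036035	1037121	+	4404000	62
CCS1	puhA	1037413	1038377	+	4404000	62
CCS1	puhB	1038669	1039680	+	4404000	62
CCS1	puhC	1039972	1040944	+	4404000	62
CCS1	hyp	1041236	1042238	+	4404000	62
CCS1	ascF	1042530	1043250	+	4404000	62
CCS1	puhE	1043542	1044640	+	4404000	62
CCS1	hemA	1044932	1045800	+	4404000	62
CCS1	rpoB	2700001	2700900	+	4404000	62
CCS1	ftsZ	2900001	2900900	+	4404000	62
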