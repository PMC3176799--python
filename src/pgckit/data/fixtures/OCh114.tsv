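replicon_id	gene	start	end	strand	replicon_length	gc_percent
OCh114	gyrA	150001	150900	+	4331200	58
OCh114	recA	400001	400900	+	4331200	58
OCh114	dnaK	650001	650900	+	4331200	58
OCh114	bchI	1000001	1000781	+	4331200	58
OCh114	bchD	1000973	1001881	+	4331200	58
OCh114	bchO	1002073	1003112	+	4331200	58
OCh114	bchP	1003304	1004245	+	4331200	58
OCh114	bchG	1004437	1005464	+	4331200	58
OCh114	ppsR	1005656	1006543	+	4331200	58
OCh114	ppaA	1006735	1007517	+	4331200	58
OCh114	bchF	1007709	1008489	+	4331200	58
OCh114	bchN	1008681	1009581	+	4331200	58
OCh114	bchB	1009773	1010684	+	4331200	58
OCh114	bchH	1010876	1011693	+	4331200	58
OCh114	bchL	1011885	1012660	+	4331200	58
OCh114	bchM	1012852	1013751	+	4331200	58
OCh114	lhaA	1013943	1014754	+	4331200	58
OCh114	puhA	1014946	1015749	+	4331200	58
OCh114	puhB	1015941	1016942	+	4331200	58
OCh114	puhC	1017134	1017907	+	4331200	58
OCh114	hyp	1018099	1019019	+	4331200	58
OCh114	ascF	1019211	1019910	+	4331200	58
OCh114	puhE	1020102	1021147	+	4331200	58
OCh114	hemA	1021339	1022398	+	4331200	58
OCh114	crtA	1022590	1023611	+	4331200	58
OCh114	crtI	1023803	1024779	+	4331200	58
OCh114	crtB	1024971	1025769	+	4331200	58
OCh114	crtK	1025961	1026978	+	4331200	58
OCh114	hyp	1027170	1027945	+	4331200	58
OCh114	crtC	1028137	1029090	+	4331200	58
OCh114	crtD	1029282	1030375	+	4331200	58
OCh114	crtE	1030567	1031326	+	4331200	58
OCh114	crtF	1031518	1032485	+	4331200	58
OCh114	bchC	1032677	1033423	+	4331200	58
OCh114	bchX	1033615	1034426	+	4331200	58
OCh114	bchY	1034618	1035489	+	4331200	58
OCh114	bchZ	1035680	1036460	+	4331200	58
OCh114	pufQ	1036651	1037712	+	4331200	58
OCh114	pufB	1037903	1038852	+	4331200	58
OCh114	pufA	1039043	1040085	+	4331200	58
OCh114	pufL	1040276	1041236	+	4331200	58
OCh114	pufM	1041427	1042275	+	4331200	58
OCh114	pufC	1042466	1043525	+	4331200	58
OCh114	dxps	1043716	1044600	+	4331200	58
OCh114	rpoB	2700001	2700900	+	4331200	58
OCh114	ftsZ	2900001	2900900	+	4331200	58
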