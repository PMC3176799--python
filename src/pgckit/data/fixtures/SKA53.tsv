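replicon_id	gene	start	end	strand	replicon_length	gc_percent
SKA53	gyrA	150001	150900	+	3063700	59
SKA53	recA	400001	400900	+	3063700	59
SKA53	dnaK	650001	650900	+	3063700	59
SKA53	crtA	1000001	1000872	+	3063700	59
SKA53	crtI	1001064	1001795	+	3063700	59
SKA53	crtB	1001987	1003070	+	3063700	59
SKA53	crtC	1003262	1004334	+	3063700	59
SKA53	crtD	1004526	1005426	+	3063700	59
SKA53	crtE	1005618	1006432	+	3063700	59
SKA53	crtF	1006624	1007492	+	3063700	59
SKA53	bchC	1007684	1008639	+	3063700	59
SKA53	bchX	1008831	1009873	+	3063700	59
SKA53	bchY	1010064	1011097	+	3063700	59
SKA53	bchZ	1011288	1012032	+	3063700	59
SKA53	pufQ	1012223	1013313	+	3063700	59
SKA53	pufB	1013504	1014340	+	3063700	59
SKA53	pufA	1014531	1015295	+	3063700	59
SKA53	pufL	1015486	1016495	+	3063700	59
SKA53	pufM	1016686	1017584	+	3063700	59
SKA53	dxps	1017775	1018761	+	3063700	59
SKA53	bchI	1018952	1019938	+	3063700	59
SKA53	bchD	1020129	1021084	+	3063700	59
SKA53	bchO	1021275	1022110	+	3063700	59
SKA53	bchP	1022301	1023129	+	3063700	59
SKA53	bchG	1023320	1024397	+	3063700	59
SKA53	ppsR	1024588	1025364	+	3063700	59
SKA53	ppaA	1025555	1026322	+	3063700	59
SKA53	bchF	1026513	1027421	+	3063700	59
SKA53	bchN	1027612	1028578	+	3063700	59
SKA53	bchB	1028769	1029850	+	3063700	59
SKA53	bchH	1030041	1030938	+	3063700	59
SKA53	bchL	1031129	1032227	+	3063700	59
SKA53	bchM	1032418	1033296	+	3063700	59
SKA53	lhaA	1033487	1034499	+	3063700	59
SKA53	puhA	1034690	1035771	+	3063700	59
SKA53	puhB	1035962	1036714	+	3063700	59
SKA53	puhC	1036905	1037902	+	3063700	59
SKA53	hyp	1038093	1039014	+	3063700	59
SKA53	ascF	1039205	1039970	+	3063700	59
SKA53	puhE	1040161	1041200	+	3063700	59
SKA53	hemA	2000001	2000900	+	3063700	59
SKA53	rpoB	2700001	2700900	+	3063700	59
SKA53	ftsZ	2900001	2900900	+	3063700	59
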