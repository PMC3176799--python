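replicon_id	gene	start	end	strand	replicon_length	gc_percent
Och149	gyrA	150001	150900	+	4678900	57
Och149	recA	400001	400900	+	4678900	57
Och149	dnaK	650001	650900	+	4678900	57
Och149	bchI	1000001	1001062	+	4678900	57
Och149	bchD	1001314	1002258	+	4678900	57
Och149	bchO	1002510	1003537	+	4678900	57
Och149	bchP	1003789	1004494	+	4678900	57
Och149	bchG	1004745	1005647	+	4678900	57
Och149	ppsR	1005898	1006672	+	4678900	57
Och149	ppaA	1006923	1007929	+	4678900	57
Och149	bchF	1008180	1009223	+	4678900	57
Och149	bchN	1009474	1010245	+	4678900	57
Och149	bchB	1010496	1011225	+	4678900	57
Och149	bchH	1011476	1012350	+	4678900	57
Och149	bchL	1012601	1013380	+	4678900	57
Och149	bchM	1013631	1014524	+	4678900	57
Och149	lhaA	1014775	1015726	+	4678900	57
Och149	puhA	1015977	1016714	+	4678900	57
Och149	puhB	1016965	1017703	+	4678900	57
Och149	puhC	1017954	1018925	+	4678900	57
Och149	hyp	1019176	1019936	+	4678900	57
Och149	ascF	1020187	1020928	+	4678900	57
Och149	puhE	1021179	1021950	+	4678900	57
Och149	hemA	1022201	1023281	+	4678900	57
Och149	rpaA	1023532	1024283	+	4678900	57
Och149	rpaB	1024534	1025560	+	4678900	57
Och149	crtA	1025811	1026904	+	4678900	57
Och149	crtI	1027155	1028035	+	4678900	57
Och149	crtB	1028286	1029291	+	4678900	57
Och149	crtK	1029542	1030399	+	4678900	57
Och149	hyp	1030650	1031450	+	4678900	57
Och149	crtC	1031701	1032443	+	4678900	57
Och149	crtD	1032694	1033589	+	4678900	57
Och149	crtE	1033840	1034931	+	4678900	57
Och149	crtF	1035182	1035965	+	4678900	57
Och149	bchC	1036216	1037028	+	4678900	57
Och149	bchX	1037279	1038122	+	4678900	57
Och149	bchY	1038373	1039172	+	4678900	57
Och149	bchZ	1039423	1040488	+	4678900	57
Och149	pufQ	1040739	1041572	+	4678900	57
Och149	pufB	1041823	1042547	+	4678900	57
Och149	pufA	1042798	1043758	+	4678900	57
Och149	pufL	1044009	1044788	+	4678900	57
Och149	pufM	1045039	1046010	+	4678900	57
Och149	pufC	1046261	1047066	+	4678900	57
Och149	dxps	1047317	1048300	+	4678900	57
Och149	rpoB	2700001	2700900	+	4678900	57
Och149	ftsZ	2900001	2900900	+	4678900	57
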