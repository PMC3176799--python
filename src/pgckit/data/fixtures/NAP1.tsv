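replicon_id	gene	start	end	strand	replicon_length	gc_percent
NAP1	gyrA	150001	150900	+	3265300	61
NAP1	recA	400001	400900	+	3265300	61
NAP1	dnaK	650001	650900	+	3265300	61
NAP1	crtC	1000001	1000907	+	3265300	61
NAP1	crtD	1001239	1002073	+	3265300	61
NAP1	crtF	1002405	1003181	+	3265300	61
NAP1	bchC	1003513	1004452	+	3265300	61
NAP1	bchX	1004784	1005758	+	3265300	61
NAP1	bchY	1006090	1006908	+	3265300	61
NAP1	bchZ	1007240	1008098	+	3265300	61
NAP1	pufB	1008430	1009224	+	3265300	61
NAP1	pufA	1009556	1010478	+	3265300	61
NAP1	pufL	1010810	1011829	+	3265300	61
NAP1	pufM	1012161	1012959	+	3265300	61
NAP1	bchI	1013291	1014124	+	3265300	61
NAP1	bchD	1014456	1015343	+	3265300	61
NAP1	bchO	1015675	1016536	+	3265300	61
NAP1	bchP	1016868	1017587	+	3265300	61
NAP1	bchG	1017919	1018760	+	3265300	61
NAP1	ppsR	1019092	1020136	+	3265300	61
NAP1	ppaA	1020468	1021437	+	3265300	61
NAP1	bchF	1021769	1022862	+	3265300	61
NAP1	bchN	1023194	1024089	+	3265300	61
NAP1	bchB	1024421	1025305	+	3265300	61
NAP1	bchH	1025637	1026682	+	3265300	61
NAP1	bchL	1027014	1027748	+	3265300	61
NAP1	bchM	1028080	1029088	+	3265300	61
NAP1	lhaA	1029420	1030239	+	3265300	61
NAP1	puhA	1030571	1031303	+	3265300	61
NAP1	puhB	1031635	1032716	+	3265300	61
NAP1	puhC	1033047	1033932	+	3265300	61
NAP1	hyp	1034263	1035248	+	3265300	61
NAP1	ascF	1035579	1036596	+	3265300	61
NAP1	puhE	1036927	1037862	+	3265300	61
NAP1	hemA	1038193	1038900	+	3265300	61
NAP1	crtI	2000001	2000900	+	3265300	61
NAP1	crtB	2025001	2025900	-	3265300	61
NAP1	crtE	2050001	2050900	+	3265300	61
NAP1	crtY	2075001	2075900	-	3265300	61
NAP1	crtZ	2100001	2100900	+	3265300	61
NAP1	rpoB	2700001	2700900	+	3265300	61
NAP1	ftsZ	2900001	2900900	+	3265300	61
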