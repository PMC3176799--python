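replicon_id	gene	start	end	strand	replicon_length	gc_percent
Roseovarius217	gyrA	150001	150900	+	4762600	60
Roseovarius217	recA	400001	400900	+	4762600	60
Roseovarius217	dnaK	650001	650900	+	4762600	60
Roseovarius217	bchI	1000001	1000942	+	4762600	60
Roseovarius217	bchD	1001203	1002054	+	4762600	60
Roseovarius217	bchO	1002315	1003325	+	4762600	60
Roseovarius217	bchP	1003586	1004428	+	4762600	60
Roseovarius217	bchG	1004689	1005746	+	4762600	60
Roseovarius217	ppsR	1006007	1007005	+	4762600	60
Roseovarius217	ppaA	1007266	1008210	+	4762600	60
Roseovarius217	bchF	1008471	1009326	+	4762600	60
Roseovarius217	bchN	1009587	1010593	+	4762600	60
Roseovarius217	bchB	1010854	1011688	+	4762600	60
Roseovarius217	bchH	1011949	1012671	+	4762600	60
Roseovarius217	bchL	1012932	1013853	+	4762600	60
Roseovarius217	bchM	1014114	1014956	+	4762600	60
Roseovarius217	lhaA	1015217	1015991	+	4762600	60
Roseovarius217	puhA	1016252	1017292	+	4762600	60
Roseovarius217	puhB	1017553	1018299	+	4762600	60
Roseovarius217	puhC	1018560	1019576	+	4762600	60
Roseovarius217	hyp	1019837	1020872	+	4762600	60
Roseovarius217	ascF	1021133	1022197	+	4762600	60
Roseovarius217	puhE	1022458	1023318	+	4762600	60
Roseovarius217	hemA	1023579	1024466	+	4762600	60
Roseovarius217	dxps	1024727	1025798	-	4762600	60
Roseovarius217	pufC	1026059	1026828	-	4762600	60
Roseovarius217	pufM	1027089	1027927	-	4762600	60
Roseovarius217	pufL	1028187	1029240	-	4762600	60
Roseovarius217	pufA	1029500	1030345	-	4762600	60
Roseovarius217	pufB	1030605	1031528	-	4762600	60
Roseovarius217	pufQ	1031788	1032883	-	4762600	60
Roseovarius217	bchZ	1033143	1034025	-	4762600	60
Roseovarius217	bchY	1034285	1035097	-	4762600	60
Roseovarius217	bchX	1035357	1036327	-	4762600	60
Roseovarius217	bchC	1036587	1037298	-	4762600	60
Roseovarius217	crtF	1037558	1038288	-	4762600	60
Roseovarius217	crtE	1038548	1039248	-	4762600	60
Roseovarius217	crtD	1039508	1040323	-	4762600	60
Roseovarius217	crtC	1040583	1041609	-	4762600	60
Roseovarius217	crtB	1041869	1042870	-	4762600	60
Roseovarius217	crtI	1043130	1043886	-	4762600	60
Roseovarius217	crtA	1044146	1045100	-	4762600	60
Roseovarius217	rpoB	2700001	2700900	+	4762600	60
Roseovarius217	ftsZ	2900001	2900900	+	4762600	60
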