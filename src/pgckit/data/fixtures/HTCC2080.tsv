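replicon_id	gene	start	end	strand	replicon_length	gc_percent
HTCC2080	gyrA	150001	150900	+	3576100	51
HTCC2080	recA	400001	400900	+	3576100	51
HTCC2080	dnaK	650001	650900	+	3576100	51
HTCC2080	bluf	1000001	1000992	+	3576100	51
HTCC2080	ascF	1001392	1002113	+	3576100	51
HTCC2080	bchI	1002513	1003455	+	3576100	51
HTCC2080	bchD	1003855	1004685	+	3576100	51
HTCC2080	bchO	1005085	1005889	+	3576100	51
HTCC2080	bchP	1006289	1007007	+	3576100	51
HTCC2080	bchG	1007407	1008363	+	3576100	51
HTCC2080	crtJ	1008763	1009574	+	3576100	51
HTCC2080	bchF	1009974	1011004	+	3576100	51
HTCC2080	bchN	1011404	1012434	+	3576100	51
HTCC2080	bchB	1012834	1013777	+	3576100	51
HTCC2080	bchH	1014177	1015120	+	3576100	51
HTCC2080	bchL	1015520	1016546	+	3576100	51
HTCC2080	bchM	1016946	1017870	+	3576100	51
HTCC2080	lhaA	1018270	1019058	+	3576100	51
HTCC2080	puhA	1019458	1020356	+	3576100	51
HTCC2080	puhB	1020756	1021582	+	3576100	51
HTCC2080	puhC	1021982	1022692	+	3576100	51
HTCC2080	puhE	1023092	1024167	+	3576100	51
HTCC2080	hemN	1024567	1025327	+	3576100	51
HTCC2080	pufA	1025727	1026718	-	3576100	51
HTCC2080	pufB	1027118	1028190	-	3576100	51
HTCC2080	pufC	1028590	1029646	-	3576100	51
HTCC2080	pufM	1030046	1030767	-	3576100	51
HTCC2080	pufL	1031167	1031915	-	3576100	51
HTCC2080	bchZ	1032315	1033317	-	3576100	51
HTCC2080	bchY	1033717	1034590	-	3576100	51
HTCC2080	bchX	1034990	1035798	-	3576100	51
HTCC2080	bchC	1036198	1036974	-	3576100	51
HTCC2080	crtF	1037374	1038184	-	3576100	51
HTCC2080	crtE	1038584	1039659	-	3576100	51
HTCC2080	crtC	1040059	1041011	-	3576100	51
HTCC2080	crtB	1041410	1042197	-	3576100	51
HTCC2080	crtI	1042596	1043600	-	3576100	51
HTCC2080	crtD	2000001	2000900	+	3576100	51
HTCC2080	rpoB	2700001	2700900	+	3576100	51
HTCC2080	ftsZ	2900001	2900900	+	3576100	51
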