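# pgckit gene catalog v1
# symbol	category	synonyms	pathway_roles
bchB	bch		bchl_biosynthesis
bchC	bch		bchl_biosynthesis
bchD	bch		bchl_biosynthesis
bchE	bch		bchl_biosynthesis
bchF	bch		bchl_biosynthesis
bchG	bch		bchl_biosynthesis
bchH	bch		bchl_biosynthesis
bchI	bch		bchl_biosynthesis
bchJ	bch		bchl_biosynthesis
bchL	bch		bchl_biosynthesis
bchM	bch		bchl_biosynthesis
bchN	bch		bchl_biosynthesis
bchO	bch		bchl_biosynthesis
bchP	bch		bchl_biosynthesis
bchX	bch		bchl_biosynthesis
bchY	bch		bchl_biosynthesis
bchZ	bch		bchl_biosynthesis
ascF	bch	acsF	bchl_biosynthesis
pufQ	puf
pufB	puf
pufA	puf
pufL	puf
pufM	puf
pufC	puf
pufX	puf
puhA	puh
puhB	puh
puhC	puh
puhE	puh
lhaA	assembly	IhaA
crtA	crt		spheroidenone
crtI	crt		spheroidenone,spirilloxanthin
crtB	crt		spheroidenone,spirilloxanthin
crtC	crt		spheroidenone,spirilloxanthin
crtD	crt		spheroidenone,spirilloxanthin
crtE	crt		spirilloxanthin
crtF	crt		spheroidenone,spirilloxanthin
crtY	crt		zeaxanthin
crtZ	crt		zeaxanthin
crtW	crt		zeaxanthin
crtK	crt
crtJ	regulatory
ppsR	regulatory
ppaA	regulatory
bluf	regulatory	BLUF
hemA	precursor		bchl_biosynthesis
hemN	precursor		bchl_biosynthesis
dxps	precursor	dxs,DXPS
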