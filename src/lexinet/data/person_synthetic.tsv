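# Synthetic demonstration wordlist: words for 'person' in Germanic, Romance
# and Slavic languages.  Forms are real lexemes in broad IPA-style tokens;
# the selection was hand-assembled for this package (synthetic stand-in, not
# an excerpt of any published dataset).  BORROWED marks the well-known Latin
# loans (persona -> Germanic/Slavic, humanus -> English).
ID	DOCULECT	FAMILY	CONCEPT	FORM	TOKENS	COGID	BORROWED
p01	Italian	Romance	person	persona	p e r s o n a	persona	0
p02	Spanish	Romance	person	persona	p e r s o n a	persona	0
p03	French	Romance	person	personne	p ɛ r s ɔ n	persona	0
p04	Romanian	Romance	person	persoană	p e r s o a n ə	persona	0
p05	Catalan	Romance	person	persona	p ə r s o n ə	persona	0
p06	Occitan	Romance	person	persona	p e r s u n ɔ	persona	0
p07	Galician	Romance	person	persoa	p e r s o a	persona	0
p08	Portuguese	Romance	person	pessoa	p e s o a	persona	0
p09	English	Germanic	person	person	p ə r s ə n	persona	1
p10	German	Germanic	person	Person	p ɛ r z o n	persona	1
p11	Dutch	Germanic	person	persoon	p ə r s o n	persona	1
p12	Russian	Slavic	person	persona	p e r s o n a	persona	1
p13	Polish	Slavic	person	persona	p e r s o n a	persona	1
p14	German	Germanic	person	Mensch	m ɛ n ʃ	mensch	0
p15	Dutch	Germanic	person	mens	m ɛ n s	mensch	0
p16	Low_German	Germanic	person	Minsch	m ɪ n ʃ	mensch	0
p17	Frisian	Germanic	person	minske	m ɪ n s k ə	mensch	0
p18	Swedish	Germanic	person	människa	m ɛ n i ʃ a	mensch	0
p19	Danish	Germanic	person	menneske	m e n ə s k ə	mensch	0
p20	Czech	Slavic	person	člověk	tʃ l o v ɛ k	chelovek	0
p21	Slovak	Slavic	person	človek	tʃ l o v e k	chelovek	0
p22	Slovenian	Slavic	person	človek	tʃ l o v e k	chelovek	0
p23	Russian	Slavic	person	čelovek	tʃ e l o v e k	chelovek	0
p24	Polish	Slavic	person	człowiek	tʃ w o v j e k	chelovek	0
p25	Serbian	Slavic	person	čovek	tʃ o v e k	chelovek	0
p26	Croatian	Slavic	person	čovjek	tʃ o v j e k	chelovek	0
p27	Italian	Romance	person	uomo	u o m o	homo	0
p28	Venetian	Romance	person	omo	o m o	homo	0
p29	French	Romance	person	homme	ɔ m	homo	0
p30	Romanian	Romance	person	om	o m	homo	0
p31	Italian	Romance	person	umano	u m a n o	humanus	0
p32	Spanish	Romance	person	humano	u m a n o	humanus	0
p33	English	Germanic	person	human	j u m ə n	humanus	1
p34	Serbian	Slavic	person	lice	l i ts e	lice	0
p35	Bulgarian	Slavic	person	lice	l i ts e	lice	0
p36	Ukrainian	Slavic	person	ljudyna	l j u d ɪ n a	ljud	0
p37	French	Romance	person	gens	ʒ ɑ̃	gens	0
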