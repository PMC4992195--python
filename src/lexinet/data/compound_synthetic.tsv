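# Word-formation example: the German word family around Krankheitsverlauf
# 'disease progression' = (krank + -heit) + (ver- + Lauf).  Broad IPA-style
# tokens with morpheme boundaries (synthetic fixture assembled for this
# package).  The compound should surface as an articulation hub whose
# neighbor groups support its two immediate parts.
ID	DOCULECT	FAMILY	CONCEPT	FORM	TOKENS	COGID	BORROWED
k01	German	Germanic	sick	krank	k r a n k	krank	0
k02	German	Germanic	sickness	Krankheit	k r a n k + h a i t	krankheit	0
k03	German	Germanic	course	Verlauf	f ɛ r + l a u f	verlauf	0
k04	German	Germanic	disease_course	Krankheitsverlauf	k r a n k + h a i t + f ɛ r + l a u f	krankheitsverlauf	0
k05	German	Germanic	run	laufen	l a u f	lauf	0
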