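# Worked partial-cognacy example: the bimorphemic words for 'moon' in
# Mandarin (yuè liàng, "moon" + "shine") and Cantonese (jyut6 gwong1,
# "moon" + "light").  The first morphemes are cognate, the second are not.
# Broad IPA-style tokens with tone digits (synthetic fixture tokens).
ID	DOCULECT	FAMILY	CONCEPT	FORM	TOKENS	COGID	BORROWED
m01	Mandarin	Sinitic	moon	yuè-liàng	ɥ ɛ 4 + l i a ŋ 4	moon	0
m02	Cantonese	Sinitic	moon	jyut6-gwong1	j ʏ t 6 + k w ɔ ŋ 1	moon	0
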