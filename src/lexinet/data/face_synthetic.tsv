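# Synthetic demonstration wordlist: dialect words for 'face' in 20 Chinese
# dialect varieties (synthetic stand-in assembled for this package).  Three
# variants occur: a liǎn-type word, a miàn-type word of different origin,
# and one fused liǎn-miàn form; tone digits are separate tokens.
ID	DOCULECT	FAMILY	CONCEPT	FORM	TOKENS	COGID	BORROWED
f01	Beijing	Sinitic	face	lian3	l i a n 3	lian	0
f02	Jinan	Sinitic	face	lia3	l i ã 3	lian	0
f03	Xian	Sinitic	face	nian3	n i a n 3	lian	0
f04	Taiyuan	Sinitic	face	lie3	l i e 3	lian	0
f05	Chengdu	Sinitic	face	nian3	n i a n 3	lian	0
f06	Wuhan	Sinitic	face	lian3	l i a n 3	lian	0
f07	Changsha	Sinitic	face	lie3	l i ẽ 3	lian	0
f08	Nanchang	Sinitic	face	lien3	l i ɛ n 3	lian	0
f09	Hangzhou	Sinitic	face	lie2	l i e 2	lian	0
f10	Kunming	Sinitic	face	lie3	l i ɛ 3	lian	0
f11	Guangzhou	Sinitic	face	min6	m i n 6	mian	0
f12	Hong_Kong	Sinitic	face	min6	m i n 6	mian	0
f13	Taishan	Sinitic	face	min5	m i n 5	mian	0
f14	Fuzhou	Sinitic	face	ming5	m i ŋ 5	mian	0
f15	Shantou	Sinitic	face	ming5	m i ŋ 5	mian	0
f16	Xiamen	Sinitic	face	min5	m i n 5	mian	0
f17	Shanghai	Sinitic	face	mi6	m i 6	mian	0
f18	Suzhou	Sinitic	face	mi6	m i 6	mian	0
f19	Meixian	Sinitic	face	min4	m i n 4	mian	0
f20	Wenzhou	Sinitic	face	lian3-min6	l i a n 3 + m i n 6	lianmian	0
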