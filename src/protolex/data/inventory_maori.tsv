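symbol	class	orthography	short_counterpart
p	consonant	p
t	consonant	t
k	consonant	k
m	consonant	m
n	consonant	n
ng	consonant	ng
wh	consonant	wh
r	consonant	r
h	consonant	h
w	consonant	w
a	short_vowel	a
e	short_vowel	e
i	short_vowel	i
o	short_vowel	o
u	short_vowel	u
aː	long_vowel	ā	a
eː	long_vowel	ē	e
iː	long_vowel	ī	i
oː	long_vowel	ō	o
uː	long_vowel	ū	u
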