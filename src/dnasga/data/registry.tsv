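key	gi	organism	seq_class	labeling	kind	primitive	generator
S02.a	45269853	Saccharomyces cerevisiae	TS	D	field	x^3+ax^2+bx+b	x^6+x^5+1
S02.b	45269853	Saccharomyces cerevisiae	TS	B	ring	x^6+x^4+x^3+x+1	x^6+2x^5+x^4+x^3+3x+1
S02.c	78096542	Triticum aestivum	TS*	D	field	x^3+bx^2+x+a	x^6+x^5+x^4+x+1
S02.d	78096542	Triticum aestivum	TS*	C	ring	x^6+x^5+x^4+x+1	x^6+x^5+x^4+2x^2+3x+1
S02.e	632733	Nicotiana tabacum	TS*	A	ring	x^6+x^5+x^2+x+1	x^6+3x^5+2x^4+x^2+x+1
S02.f	632733	Nicotiana tabacum	TS*	A	ring	x^6+x^5+x^3+x^2+1	x^6+3x^5+x^3+x^2+2x+1
S02.g	7328566	Citrus sinensis	TS	B	ring	x^6+x^5+1	x^6+3x^5+2x^3+1
S02.h	186509758	Arabidopsis thaliana	TS*	A	ring	x^6+x^5+x^3+x^2+1	x^6+3x^5+x^3+x^2+2x+1
S02.i	832917	Saccharomyces cerevisiae	PM	A	ring	x^6+x^5+x^2+x+1	x^6+3x^5+2x^4+x^2+x+1
S02.j	12587	Homo sapiens	TS	C	ring	x^6+x^5+1	x^6+3x^5+2x^3+1
MDH	30695458	Arabidopsis thaliana	?	C	ring	x^10+x^9+x^8+x^7+x^6+x^4+x^3+x+1	x^10+x^9+x^8+3x^7+x^6+x^4+x^3+3x+1
T4.a	217937	Ipomoea batatas	TS	B	field	x^3+ax^2+ax+a	x^6+x^5+x^3+x^2+1
T4.b	51093376	Polistes dominulus	TS	D	field	x^3+ax^2+bx+b	x^6+x^5+1
T4.c	16740522	Mesobuthus martensii	TS	A	ring	x^6+x^5+x^4+x+1	x^6+x^5+x^4+2x^2+3x+1
T4.d	25140446	Homo sapiens	?	B	ring	x^6+x^5+1	x^6+3x^5+2x^3+1
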