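finger_index	res_m2	res_m1	res_p2	res_p3	res_p6	full_sequence
1	S	R	D	E	T	TGEKPYECKECGKAFRDELTHLRTHSG
2	S	A	S	N	Q	TGEKPYVCRECGRGFASNQGLNRHKRT
3	S	V	S	T	Y	TGEKPYVCRECGRGFVSSTYLNRHQRT
4	S	K	D	N	R	TGEKPYVCRECGRGFKDDNRLNRHART
5	S	A	S	N	Q	TGEKPYVCRECGRGFASNQGLNRHKRT
6	S	Q	G	H	V	TGEKPYVCRECGRGFQGGHVLNRHLRT
7	S	A	S	N	Q	TGEKPYVCRECGRGFASNQGLNRHKRT
8	S	T	N	E	K	TGEKPYVCRECGRGFTNNEKLNRHGRT
9	S	A	S	N	Q	TGEKPYVCRECGRGFASNQGLNRHKRT
10	S	N	D	V	W	TGEKPYVCRECGRGFNDDVWLNRHMRT
11	S	E	S	K	L	TGEKPYVCRECGRGFESSKLLNRHVRT
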