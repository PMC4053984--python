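finger_index	res_m2	res_m1	res_p2	res_p3	res_p6	full_sequence
1	S	R	D	E	T	TGEKPYECKECGKAFRDELTHLRTHSG
2	S	D	S	N	R	TGEKPYVCRECGRGFDSSNRLNRHRRT
3	S	A	S	N	K	TGEKPYVCRECGRGFASSNKLNRHTRT
4	S	Q	G	H	V	TGEKPYVCRECGRGFQGGHVLNRHLRT
5	S	V	S	T	Y	TGEKPYVCRECGRGFVSSTYLNRHQRT
6	S	A	S	N	K	TGEKPYVCRECGRGFASSNKLNRHTRT
7	S	K	D	N	R	TGEKPYVCRECGRGFKDDNRLNRHART
8	S	N	D	V	W	TGEKPYVCRECGRGFNDDVWLNRHMRT
9	S	T	N	E	K	TGEKPYVCRECGRGFTNNEKLNRHGRT
10	S	N	D	V	W	TGEKPYVCRECGRGFNDDVWLNRHMRT
11	S	E	S	K	L	TGEKPYVCRECGRGFESSKLLNRHVRT
12	S	G	H	R	M	TGEKPYVCRECGRGFGHHRMLNRHCRT
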