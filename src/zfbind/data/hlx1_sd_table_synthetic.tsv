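position	sd
1	0.03
2	0.038
3	0.045
4	0.052
5	0.16
6	0.182
7	0.204
8	0.227
9	0.249
10	0.45
11	0.46
12	0.47
13	0.48
14	0.49
15	0.5
16	0.51
17	0.52
18	0.271
19	0.293
20	0.316
21	0.338
22	0.36
23	0.06
24	0.068
25	0.075
26	0.082
27	0.09
28	0.098
29	0.105
30	0.112
31	0.12
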