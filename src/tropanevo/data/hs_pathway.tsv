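index	enzyme	substrate	product	segment
1	PMT	1	2	tropane-ring
2	MPO	2	3	tropane-ring
3	PYKS	3	4	tropane-ring
4	CYP82M3	4	5	tropane-ring
5	ArAT4	7	8	PLA-glucoside
6	PPAR	8	9	PLA-glucoside
7	UGT1	9	10	PLA-glucoside
8	TRI	5	6	medicinal
9	LS	6	11	medicinal
10	CYP80F1	11	12	medicinal
11	HDH	12	13	medicinal
12	H6H	13	14	medicinal
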