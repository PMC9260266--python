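band_type	ck_h	ck_m	treat_h	treat_m	root_15uM	root_50uM	root_100uM	leaf_15uM	leaf_50uM	leaf_100uM
B1	1	1	0	1	0	1	1	0	2	2
B2	1	0	0	1	1	0	0	1	0	0
B3	1	0	0	0	2	6	4	3	7	3
B4	1	1	0	0	0	0	0	0	0	0
C1	0	1	1	1	3	6	8	4	8	9
C2	0	1	1	0	0	0	1	0	0	1
C3	0	0	1	0	4	12	9	5	10	13
C4	0	0	1	1	0	2	7	0	3	6
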