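type_i	type_j	epsilon	sigma
H	H	0.0450	1.600
H	C	0.0687	2.800
H	N	0.0849	2.450
H	O	0.0835	2.375
H	S	0.1061	2.750
C	C	0.1050	4.000
C	N	0.1296	3.650
C	O	0.1276	3.575
C	S	0.1620	3.950
N	N	0.1600	3.300
N	O	0.1575	3.225
N	S	0.2000	3.600
O	O	0.1550	3.150
O	S	0.1969	3.525
S	S	0.2500	3.900
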