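class_i	class_j	ace
CH	CH	-1.20
CH	CP	-0.40
CH	N	0.30
CH	O	0.40
CH	S	-0.80
CP	CP	-0.10
CP	N	0.10
CP	O	0.15
CP	S	-0.30
N	N	0.60
N	O	0.50
N	S	0.20
O	O	0.70
O	S	0.25
S	S	-0.90
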