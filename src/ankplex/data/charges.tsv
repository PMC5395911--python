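residue	atom	charge
*	N	-0.35
*	CA	0.10
*	C	0.55
*	O	-0.55
*	OXT	-0.57
ARG	NE	-0.40
ARG	CZ	0.50
ARG	NH1	0.45
ARG	NH2	0.45
LYS	NZ	1.00
ASP	CG	0.14
ASP	OD1	-0.57
ASP	OD2	-0.57
GLU	CD	0.14
GLU	OE1	-0.57
GLU	OE2	-0.57
HIS	ND1	-0.40
HIS	CE1	0.30
HIS	NE2	-0.40
SER	OG	-0.55
SER	CB	0.25
THR	OG1	-0.55
THR	CB	0.25
TYR	OH	-0.55
TYR	CZ	0.25
ASN	OD1	-0.55
ASN	ND2	-0.30
ASN	CG	0.55
GLN	OE1	-0.55
GLN	NE2	-0.30
GLN	CD	0.55
TRP	NE1	-0.30
CYS	SG	-0.19
MET	SD	-0.12
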