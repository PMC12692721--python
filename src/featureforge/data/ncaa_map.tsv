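# Mapping of frequent non-canonical amino acid (ncAA) three-letter codes to
# the one-letter code of their canonical counterpart. Extensible: extra rows
# may be appended by users; codes absent from this table map to 'X'.
# Columns: three-letter code, canonical one-letter code, canonical parent.
code	one	parent3
MSE	M	MET
CSO	C	CYS
OCS	C	CYS
CSD	C	CYS
CSX	C	CYS
CME	C	CYS
SMC	C	CYS
SEP	S	SER
TPO	T	THR
PTR	Y	TYR
PCA	E	GLU
CGU	E	GLU
HYP	P	PRO
MLY	K	LYS
MLZ	K	LYS
M3L	K	LYS
KCX	K	LYS
LLP	K	LYS
ALY	K	LYS
MEN	N	ASN
FME	M	MET
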