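codon	aa	degeneracy
AAA	K	112
AAC	N	112
AAG	K	112
AAT	N	112
ACA	T	114
ACC	T	114
ACG	T	114
ACT	T	114
AGA	R	212
AGC	S	112
AGG	R	212
AGT	S	112
ATA	I	113
ATC	I	113
ATG	M	111
ATT	I	113
CAA	Q	112
CAC	H	112
CAG	Q	112
CAT	H	112
CCA	P	114
CCC	P	114
CCG	P	114
CCT	P	114
CGA	R	214
CGC	R	114
CGG	R	214
CGT	R	114
CTA	L	214
CTC	L	114
CTG	L	214
CTT	L	114
GAA	E	112
GAC	D	112
GAG	E	112
GAT	D	112
GCA	A	114
GCC	A	114
GCG	A	114
GCT	A	114
GGA	G	114
GGC	G	114
GGG	G	114
GGT	G	114
GTA	V	114
GTC	V	114
GTG	V	114
GTT	V	114
TAC	Y	112
TAT	Y	112
TCA	S	114
TCC	S	114
TCG	S	114
TCT	S	114
TGC	C	112
TGG	W	111
TGT	C	112
TTA	L	212
TTC	F	112
TTG	L	212
TTT	F	112
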