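# Codon usage for Escherichia coli K-12 (relative fractions per amino acid).
# Rounded values of the widely cited K-12 usage compilations (Kazusa codon
# usage database / Nakamura et al., NAR 28:292, 2000); fractions per amino
# acid sum to 1. Users may supply their own table in the same format.
aa	codon	fraction
A	GCG	0.36
A	GCC	0.27
A	GCA	0.21
A	GCT	0.16
R	CGC	0.40
R	CGT	0.38
R	CGG	0.10
R	CGA	0.06
R	AGA	0.04
R	AGG	0.02
N	AAC	0.55
N	AAT	0.45
D	GAT	0.63
D	GAC	0.37
C	TGC	0.55
C	TGT	0.45
Q	CAG	0.65
Q	CAA	0.35
E	GAA	0.68
E	GAG	0.32
G	GGC	0.40
G	GGT	0.34
G	GGG	0.15
G	GGA	0.11
H	CAT	0.57
H	CAC	0.43
I	ATT	0.51
I	ATC	0.42
I	ATA	0.07
L	CTG	0.50
L	TTA	0.13
L	TTG	0.13
L	CTT	0.10
L	CTC	0.10
L	CTA	0.04
K	AAA	0.76
K	AAG	0.24
M	ATG	1.00
F	TTT	0.57
F	TTC	0.43
P	CCG	0.52
P	CCA	0.19
P	CCT	0.16
P	CCC	0.13
S	AGC	0.28
S	TCT	0.15
S	TCC	0.15
S	TCG	0.15
S	AGT	0.15
S	TCA	0.12
T	ACC	0.44
T	ACG	0.27
T	ACT	0.16
T	ACA	0.13
W	TGG	1.00
Y	TAT	0.57
Y	TAC	0.43
V	GTG	0.37
V	GTT	0.28
V	GTC	0.20
V	GTA	0.15
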