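# Amino-acid composition of UniProtKB/Swiss-Prot (percent of residues),
# from the UniProtKB/Swiss-Prot release statistics. Normalized on load.
residue	percent
A	8.25
R	5.53
N	4.06
D	5.46
C	1.38
Q	3.93
E	6.72
G	7.07
H	2.27
I	5.91
L	9.65
K	5.80
M	2.41
F	3.86
P	4.74
S	6.64
T	5.35
W	1.10
Y	2.92
V	6.86
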