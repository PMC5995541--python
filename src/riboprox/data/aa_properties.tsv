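# Residue property classification used for TMD composition statistics.
# Categories deliberately overlap (a residue may be both aromatic and
# hydrophobic); edit this table to adopt alternative conventions
# (e.g. histidine as charged).
residue	properties
A	ALIPHATIC,HYDROPHOBIC
C	HYDROPHOBIC,POLAR
D	CHARGED
E	CHARGED
F	AROMATIC,HYDROPHOBIC
G
H	POLAR
I	ALIPHATIC,HYDROPHOBIC
K	CHARGED
L	ALIPHATIC,HYDROPHOBIC
M	HYDROPHOBIC
N	POLAR
P
Q	POLAR
R	CHARGED
S	POLAR
T	POLAR
V	ALIPHATIC,HYDROPHOBIC
W	AROMATIC,HYDROPHOBIC
Y	AROMATIC,POLAR
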