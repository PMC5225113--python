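# Default ARPAbet phoneme -> viseme category mapping (12 categories).
# Groupings follow the visual phoneme-similarity classes of Auer & Bernstein
# (1997, J. Acoust. Soc. Am. 102:3704): phonemes that are indistinguishable
# on the lips share a category (1-7 consonant classes, 8-12 vowel classes).
# Edit freely; ids must stay contiguous 1..K.
B	1
P	1
M	1
F	2
V	2
TH	3
DH	3
D	4
T	4
S	4
Z	4
SH	5
ZH	5
CH	5
JH	5
K	6
G	6
N	6
NG	6
L	6
Y	6
HH	6
W	7
R	7
IY	8
IH	8
EY	8
EH	8
AE	8
AA	9
AH	9
AW	9
AY	9
AO	10
OW	10
OY	10
UW	11
UH	11
ER	12
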