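phoneme,klass,vowel_height,contour,vowel_place,vowel_length,nasality,manner,voicing,affrication,sibilance,place
AA,vowel,0,1,2,0,,,,,,
AE,vowel,0,1,1,0,,,,,,
AH,vowel,1,1,1,0,,,,,,
AO,vowel,1,1,2,0,,,,,,
AW,vowel,0,2,1,1,,,,,,
AY,vowel,0,0,1,1,,,,,,
EH,vowel,1,1,0,0,,,,,,
ER,vowel,1,1,0,0,,,,,,
EY,vowel,1,1,1,0,,,,,,
IH,vowel,1,0,0,1,,,,,,
IY,vowel,2,1,0,0,,,,,,
OW,vowel,1,0,2,1,,,,,,
OY,vowel,1,2,2,1,,,,,,
UH,vowel,2,1,2,0,,,,,,
UW,vowel,2,1,2,1,,,,,,
B,consonant,,,,,0,0,1,0,0,0
CH,consonant,,,,,0,4,0,1,1,1
D,consonant,,,,,0,0,1,0,0,1
DH,consonant,,,,,0,2,0,1,0,0
F,consonant,,,,,0,2,0,1,0,0
G,consonant,,,,,0,0,1,0,0,2
HH,consonant,,,,,0,2,0,1,0,2
JH,consonant,,,,,0,4,1,1,1,1
K,consonant,,,,,0,0,0,0,0,2
L,consonant,,,,,0,3,1,0,0,1
M,consonant,,,,,1,1,1,0,0,0
N,consonant,,,,,1,1,1,0,0,1
NG,consonant,,,,,1,1,1,0,0,2
P,consonant,,,,,0,0,0,0,0,0
R,consonant,,,,,0,3,1,0,0,1
S,consonant,,,,,0,2,0,1,1,1
SH,consonant,,,,,0,2,0,1,1,1
T,consonant,,,,,0,0,0,0,0,1
TH,consonant,,,,,0,2,1,1,0,0
V,consonant,,,,,0,2,1,1,0,0
W,consonant,,,,,0,3,1,0,0,0
Y,consonant,,,,,0,3,1,0,0,1
Z,consonant,,,,,0,2,1,1,1,1
ZH,consonant,,,,,0,2,1,1,1,1
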