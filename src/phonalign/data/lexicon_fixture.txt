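;;; Fixture pronouncing lexicon in CMUDict 0.7b format.
;;; A small English vocabulary covering all 39 stress-free ARPAbet phonemes;
;;; stands in for the full CMUDict file, which can be loaded by path instead.
A  AH0
A(2)  EY1
ARE  AA1 R
BIRDS  B ER1 D Z
BITE  B AY1 T
BOOKS  B UH1 K S
BOY  B OY1
BROWN  B R AW1 N
CAT  K AE1 T
CHAIR  CH EH1 R
CHEESE  CH IY1 Z
CHILDREN  CH IH1 L D R AH0 N
COLD  K OW1 L D
COW  K AW1
DAY  D EY1
DOG  D AO1 G
DOOR  D AO1 R
EARTH  ER1 TH
EAT  IY1 T
FATHER  F AA1 DH ER0
FISH  F IH1 SH
FIVE  F AY1 V
FOOD  F UW1 D
FUN  F AH1 N
GARDEN  G AA1 R D AH0 N
GIRL  G ER1 L
GOOD  G UH1 D
GREEN  G R IY1 N
HAND  HH AE1 N D
HOUSE  HH AW1 S
IS  IH1 Z
IT'S  IH1 T S
JUDGE  JH AH1 JH
JUMP  JH AH1 M P
KEY  K IY1
KING  K IH1 NG
LARGE  L AA1 R JH
LIGHT  L AY1 T
LIVE  L IH1 V
LIVE(2)  L AY1 V
MEASURE  M EH1 ZH ER0
MILK  M IH1 L K
MINTS  M IH1 N T S
MOON  M UW1 N
MORNING  M AO1 R N IH0 NG
MOTHER  M AH1 DH ER0
MOUTH  M AW1 TH
MUSIC  M Y UW1 Z IH0 K
NIGHT  N AY1 T
NOISE  N OY1 Z
NORTH  N AO1 R TH
ON  AA1 N
ON(2)  AO1 N
ORANGE  AO1 R AH0 N JH
PEOPLE  P IY1 P AH0 L
PINCH  P IH1 N CH
PLEASURE  P L EH1 ZH ER0
POINT  P OY1 N T
RAIN  R EY1 N
READ  R IY1 D
RING  R IH1 NG
RIVER  R IH1 V ER0
ROAD  R OW1 D
SCHOOL  S K UW1 L
SHE'S  SH IY1 Z
SHEEP  SH IY1 P
SHOES  SH UW1 Z
SING  S IH1 NG
SMALL  S M AO1 L
SONG  S AO1 NG
SOUTH  S AW1 TH
SPRING  S P R IH1 NG
STRONG  S T R AO1 NG
SUMMER  S AH1 M ER0
SUN  S AH1 N
TABLE  T EY1 B AH0 L
THE  DH AH0
THE(2)  DH IY0
THESE  DH IY1 Z
THEY  DH EY1
THIN  TH IH1 N
THING  TH IH1 NG
THREE  TH R IY1
TOWN  T AW1 N
TOY  T OY1
TREE  T R IY1
USUAL  Y UW1 ZH AH0 W AH0 L
VISION  V IH1 ZH AH0 N
VOICE  V OY1 S
WATER  W AO1 T ER0
WE  W IY1
WHITE  W AY1 T
WINTER  W IH1 N T ER0
WOMAN  W UH1 M AH0 N
YELLOW  Y EH1 L OW0
YOUNG  Y AH1 NG
YOUR  Y AO1 R
ZOO  Z UW1
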