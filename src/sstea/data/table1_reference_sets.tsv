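receptor	position
ADRB2	3.32
ADRB2	3.33
ADRB2	5.42
ADRB2	5.43
ADRB2	5.46
ADRB2	6.55
ADRB2	7.35
ADRB2	7.39
PI2R	2.65
PI2R	3.28
PI2R	7.39
PI2R	7.40
CNR2	3.28
CNR2	3.31
CNR2	4.64
CNR2	5.39
C5AR	3.28
C5AR	3.32
C5AR	5.39
C5AR	5.42
C5AR	5.43
C5AR	7.35
GNRHR	2.61
GNRHR	2.64
GNRHR	2.65
GNRHR	3.32
GNRHR	5.39
GNRHR	6.58
V1AR	2.57
V1AR	2.61
V1AR	3.29
V1AR	3.32
V1AR	4.60
V1AR	5.43
V1AR	6.55
FFAR1	5.39
FFAR1	6.55
FFAR1	7.35
CCR5	1.39
CCR5	2.60
CCR5	3.32
CCR5	7.39
P2Y11	3.29
P2Y11	7.39
P2Y11	6.55
P2Y13	6.55
P2Y13	7.35
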