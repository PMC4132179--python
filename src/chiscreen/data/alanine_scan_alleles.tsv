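allele	mutation	phenotype	location	interactions
act1-101	D363A,E364A	Ts-, recessive	Side	13
act1-102	K359A,E361A	Wild type	Side	16
act1-103	E334A,R335A,K336A	Lethal, recessive	Front	26
act1-104	K315A,E316A	Wild type	Side	18
act1-105	E311A,R312A	Cs-, Ts-, recessive	Front	113
act1-106	R290A,K291A,E292A	Lethal, recessive	Side	41
act1-107	D286A,D288A	Lethal, partial dominant	Top/bottom	50
act1-108	R256A,E259A	Ts-, weakly dominant	Back	63
act1-109	E253A,R254A	Lethal, partial dominant	Front	52
act1-110	E237A,K238A	Lethal, partial dominant	Top/bottom	45
act1-111	D222A,E224A,E226A	Ts-, recessive	Side	57
act1-112	K213A,E214A,K215A	Cs-, Ts-, recessive	Front	100
act1-113	R210A,D211A	Weak Ts-, recessive	Front	21
act1-115	E195A,R196A	Wild type	Top/bottom	11
act1-116	D187A,K191A	Wild type	Back	5
act1-117	R183A,D184A	Wild type	Back	4
act1-119	R116A,E117A,K118A	Ts-, recessive	Back	12
act1-120	E99A,E100A	Ts-, recessive	Side	7
act1-121	E83A,K84A	Cs-, Ts-, recessive	Side	7
act1-122	D80A,D81A	Cs-, Ts-, recessive	Side	9
act1-123	R68A,E72A	Wild type	Back	33
act1-124	D56A,E57A	Ts-, recessive	Front	11
act1-125	K50A,D51A	Cs-, Ts-, recessive	Side	3
act1-127	E270A,D275A	Lethal, recessive	Back	19
act1-128	E241A,D244A	Lethal, partial dominant	Top/bottom	40
act1-129	R177A,D179A	Ts-, recessive	Back	10
act1-131	K61A,R62A	Lethal, partial dominant	Top/bottom	54
act1-132	R37A,R39A	Cs-, Ts-, recessive	Back	34
act1-133	D24A,D25A	Cs-, Ts-, recessive	Front	34
act1-135	E4A	Wild type	Front	9
act1-136	D2A	Wild type	ND	14
act1-159	V159N	Ts-, recessive	ATP cleft	17
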