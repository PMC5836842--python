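variant	tool	verdict
L467F	SIFT	benign
L467F	PolyPhen-2	damaging
L467F	PROVEAN	damaging
L467F	Phd-SNP	damaging
L467F	PANTHER	benign
L467F	SNP&GO	benign
L467F	OGMET	benign
R668C	SIFT	damaging
R668C	PolyPhen-2	damaging
R668C	PROVEAN	damaging
R668C	Phd-SNP	damaging
R668C	PANTHER	damaging
R668C	SNP&GO	damaging
R668C	OGMET	damaging
R1070Q	SIFT	damaging
R1070Q	PolyPhen-2	damaging
R1070Q	PROVEAN	damaging
R1070Q	Phd-SNP	benign
R1070Q	PANTHER	benign
R1070Q	SNP&GO	benign
R1070Q	OGMET	benign
E92K	SIFT	damaging
E92K	PolyPhen-2	damaging
E92K	PROVEAN	damaging
E92K	Phd-SNP	damaging
E92K	SNP&GO	damaging
E92K	PANTHER	unavailable
E92K	OGMET	unavailable
R334W	SIFT	damaging
R334W	PolyPhen-2	damaging
R334W	PROVEAN	damaging
R334W	Phd-SNP	damaging
R334W	SNP&GO	damaging
R334W	PANTHER	unavailable
R334W	OGMET	unavailable
R347P	SIFT	damaging
R347P	PolyPhen-2	damaging
R347P	PROVEAN	damaging
R347P	Phd-SNP	damaging
R347P	SNP&GO	damaging
R347P	PANTHER	unavailable
R347P	OGMET	unavailable
Q98R	SIFT	damaging
Q98R	PolyPhen-2	damaging
Q98R	PROVEAN	damaging
Q98R	Phd-SNP	damaging
Q98R	SNP&GO	damaging
Q98R	PANTHER	unavailable
Q98R	OGMET	unavailable
L1335P	SIFT	damaging
L1335P	PolyPhen-2	damaging
L1335P	PROVEAN	damaging
L1335P	Phd-SNP	damaging
L1335P	SNP&GO	damaging
L1335P	PANTHER	unavailable
L1335P	OGMET	unavailable
S1159F	SIFT	damaging
S1159F	PolyPhen-2	damaging
S1159F	PROVEAN	damaging
S1159F	Phd-SNP	damaging
S1159F	SNP&GO	damaging
S1159F	PANTHER	unavailable
S1159F	OGMET	unavailable
S1159P	SIFT	damaging
S1159P	PolyPhen-2	damaging
S1159P	PROVEAN	damaging
S1159P	Phd-SNP	damaging
S1159P	SNP&GO	damaging
S1159P	PANTHER	unavailable
S1159P	OGMET	unavailable
Y569H	SIFT	damaging
Y569H	PolyPhen-2	damaging
Y569H	PROVEAN	damaging
Y569H	Phd-SNP	damaging
Y569H	SNP&GO	damaging
Y569H	PANTHER	unavailable
Y569H	OGMET	unavailable
G461E	SIFT	damaging
G461E	PolyPhen-2	damaging
G461E	PROVEAN	damaging
G461E	Phd-SNP	damaging
G461E	SNP&GO	damaging
G461E	PANTHER	unavailable
G461E	OGMET	unavailable
N1303K	SIFT	damaging
N1303K	PolyPhen-2	damaging
N1303K	PROVEAN	damaging
N1303K	Phd-SNP	damaging
N1303K	SNP&GO	damaging
N1303K	PANTHER	damaging
N1303K	OGMET	unavailable
W1282R	SIFT	damaging
W1282R	PolyPhen-2	damaging
W1282R	PROVEAN	damaging
W1282R	Phd-SNP	damaging
W1282R	SNP&GO	damaging
W1282R	PANTHER	unavailable
W1282R	OGMET	unavailable
S945L	SIFT	damaging
S945L	PolyPhen-2	damaging
S945L	PROVEAN	damaging
S945L	Phd-SNP	damaging
S945L	SNP&GO	damaging
S945L	PANTHER	unavailable
S945L	OGMET	unavailable
R1066C	SIFT	damaging
R1066C	PolyPhen-2	damaging
R1066C	PROVEAN	damaging
R1066C	Phd-SNP	damaging
R1066C	SNP&GO	damaging
R1066C	PANTHER	damaging
R1066C	OGMET	damaging
F508del	PROVEAN	damaging
F508del	DDIG-in	damaging
L138ins	PROVEAN	damaging
L138ins	DDIG-in	damaging
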