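name	cdna_name	protein_name	mutation_class	status
3849+10kbC>T	c.3718-2477C>T		V	pathogenic
3272-16T>A	c.3140-16T>A		V	pathogenic
2789+5G>A	c.2657+5G>A		V	pathogenic
3272-11A>G	c.3140-11A>G		V	pathogenic
3874-14C>T	c.3874-14C>G		V	likely_pathogenic
E92K	c.274G>A	p.Glu92Lys	IV	pathogenic
S1159F	c.3476C>T	p.Ser1159Phe	IV	pathogenic
R334W	c.1000C>T	p.Arg334Trp	IV	pathogenic
R347P	c.1040G>C	p.Arg347Pro	IV	pathogenic
Q98R	c.293A>G	p.Gln98Arg	IV	pathogenic
L138ins	c.412_413insACT	p.Leu138dup	IV	pathogenic
L1335P	c.4004T>C	p.Leu1335Pro	IV	pathogenic
Y569H	c.1705T>C	p.Tyr569His	II	pathogenic
G461E	c.1382G>A	p.Gly461Glu	II	pathogenic
S1159P	c.3476C>T	p.Ser1159Pro	II	pathogenic
F508del	c.1521_1523delCTT	p.Phe508del	II	pathogenic
N1303K	c.3909C>G	p.Asn1303Lys	II	pathogenic
W1282R	c.3844T>C	p.Trp1282Arg	II	pathogenic
S945L	c.2834C>T	p.Ser945Leu	II	pathogenic
R1066C	c.3196C>T	p.Arg1066Cys	II	pathogenic
ex2,3del	c.54-5940_273+10250del21kb	p.Ser18_Gly91del	I	pathogenic
dup6b,10	c.(743+1_744-1)_(1584+1_1585-1)dup		I	pathogenic
2143delT	c.2012delT		I	pathogenic
394delTT	c.262_263delTT		I	pathogenic
2184insA	c.2052dupA		I	pathogenic
I1295Ffs	c.3883delA	p.Ile1295PhefsX	I	pathogenic
R1239=	c.3717G>A	p.Arg1239=	I	pathogenic
N415*	c.1240_1244delCAAAA	p.Asn415*	I	pathogenic
R785*	c.2353C>T	p.Arg785*	I	pathogenic
R709*	c.2125C>T	p.Arg709*	I	pathogenic
S466*	c.1397C>A	p.Ser466*	I	pathogenic
S1226*	c.3587C>G	p.Ser1226*	I	pathogenic
G542*	c.1624G>T	p.Gly542*	I	pathogenic
1898+1G>C	c.1766+1G>C		I	pathogenic
1716+1G>A	c.1584+1G>A		I	pathogenic
4374+1G>A	c.4242+1G>A		I	pathogenic
4374+1G>T	c.4242+1G>T		I	pathogenic
712-1G>T	c.580-1G>T		I	pathogenic
1248+1G>A	c.1116+1G>A		I	pathogenic
3821delT	c.3691delT		I	pathogenic
2118del4	c.1984_1987delCTAA		I	pathogenic
L15Ffs	c.43delC	p.Leu15PhefsX	I	pathogenic
2043delG	c.1911delG		I	pathogenic
R668C	c.2002C>T	p.Arg668Cys	none	VUS
L467F	c.1399C>T	p.Leu467Phe	none	VUS
R1070Q	c.3209G>A	p.Arg1070Gln	none	VUS
V470M	c.1408G>A	p.Val470Met	none	benign
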