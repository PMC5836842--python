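row	allele1	allele2	n	phenotype	pancreatic
1	3849+10kbC>T	F508del	8	M	sufficient
2	3849+10kbC>T	F508del;L467F	1	M	sufficient
3	3849+10kbC>T;R668C	F508del	1	M	sufficient
4	3849+10kbC>T;R668C	R1066C	1	M	sufficient
5	3849+10kbC>T;R668C	2143delT	1	M	sufficient
6	3849+10kbC>T	I1295Ffs	1	M	sufficient
7	3849+10kbC>T	S1226*	1	M	sufficient
8	3272-16T>A	R347P(;)394delTT	1	M	sufficient
9	3272-16T>A	F508del	3	M	sufficient
10	2789+5G>A	F508del;L467F	1	M	sufficient
11	2789+5G>A	ex2,3del	1	M	sufficient
12	3272-11A>G	F508del	1	M	sufficient
13	E92K	E92K	1	M	sufficient
14	E92K	F508del	7	M	sufficient
15	E92K	ex2,3del	1	M	sufficient
16	S1159P	F508del	1	S	sufficient
17	R334W	F508del	1	M	sufficient
18	R347P	W1282R	1	M	sufficient
19	L138ins	F508del	2	M	sufficient
20	L1335P	F508del	1	M	sufficient
21	I1295Ffs	F508del	1	S	sufficient
22	Y569H	F508del	1	S	insufficient
23	G461E	N1303K	1	S	insufficient
24	S1159F	S1159F	1	M	insufficient
25	Q98R	2184insA	1	M	insufficient
26	Q98R	G542*	1	M	insufficient
27	F508del	F508del	6	S	insufficient
28	F508del	W1282R	2	S	insufficient
29	F508del	S945L	2	S	insufficient
30	F508del	R1070Q;S466*	1	S	insufficient
31	F508del	ex2,3del	4	S	insufficient
32	F508del;L467F	ex2,3del	1	S	insufficient
33	F508del	2143delT	3	S	insufficient
34	F508del;L467F	2143delT	1	S	insufficient
35	F508del	2184insA	1	S	insufficient
36	F508del	N415*	1	S	insufficient
37	F508del	R1239=	2	S	insufficient
38	F508del	R785*	1	S	insufficient
39	F508del	dup6b,10	1	S	insufficient
40	F508del	R709*	1	S	insufficient
41	F508del	1898+1G>C	1	S	insufficient
42	F508del	4374+1G>A	1	S	insufficient
43	F508del	3821delT	1	S	insufficient
44	F508del	L15Ffs	1	S	insufficient
45	N1303K	N1303K	1	S	insufficient
46	N1303K	ex2,3del	1	S	insufficient
47	R785*	R1070Q;S466*	1	S	insufficient
48	ex2,3del	ex2,3del	1	S	insufficient
49	ex2,3del	2184insA	1	S	insufficient
50	ex2,3del	N415*	1	S	insufficient
51	394delTT	2184insA	1	S	insufficient
52	4374+1G>T	4374+1G>T	1	S	insufficient
53	dup6b,10	712-1G>T	1	S	insufficient
54	1716+1G>A	2043delG	1	S	insufficient
55	2118del4	1248+1G>A	1	S	insufficient
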