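# Published allele frequencies of 12 common pathogenic CFTR variants in Russian
# cohorts: the RUSeq healthy-population exome database, a Moscow-region
# population survey (Petrova), infertile Russian men with and without CBAVD,
# and the national CF-registry-derived calculated AF column (registry n = 3298).
legacy_name	rsid	RUSeq (n=1671)	Petrova (n=1327)	InfertileMen (n=6033)	NonCBAVD (n=5098)	Calculated (n=3298)
F508del	rs113993960	0.008	0.0057	0.0152	0.0113	0.0054
CFTRdele2,3(21kb)	-	n.a.	0.0004	0.0017	0.0011	0.0006
L138ins	rs397508686	0.0006	0	0.0015	0.0009	0.0002
W1282X	rs77010898	0.0006	0.0011	0.0013	0.0009	0.0002
1677delTA	rs121908776	0	n.a.	0.0007	0.0005	0.0002
3849+10kbC>T	rs75039782	0.001	n.a.	0.0007	0.0006	0.0002
E92K	rs121908751	0	0	0.0007	0.0004	0.0004
2143delT	rs121908812	0.0003	n.a.	0.0006	0.0002	0.0002
G542X	rs113993959	0.0003	n.a.	0.0005	0.0003	0.0002
2184insA	rs121908746	n.a.	n.a.	0.0005	0.0002	0.0002
N1303K	rs80034486	0.0009	n.a.	0.0003	0.0001	0.0002
R334W	rs121909011	0	n.a.	0.0003	0.0003	0.0001
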