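legacy_name	hgvs_c	hgvs_p	rsid
F508del	c.1521_1523del	p.Phe508del	rs113993960
CFTRdele2,3(21kb)	c.54-5940_273+10250del21kb	p.Ser18ArgfsX16	-
L138ins	c.413_415dup	p.Leu138dup	rs397508686
W1282X	c.3846G>A	p.Trp1282Ter	rs77010898
1677delTA	c.1545_1546delTA	p.Tyr515Ter	rs121908776
3849+10kbC>T	c.3718-2477C>T	-	rs75039782
E92K	c.274G>A	p.Glu92Lys	rs121908751
2143delT	c.2012del	p.Leu671Ter	rs121908812
G542X	c.1624G>T	p.Gly542Ter	rs113993959
2184insA	c.2052dup	p.Gln685ThrfsTer4	rs121908746
N1303K	c.3909C>G	p.Asn1303Lys	rs80034486
R334W	c.1000C>T	p.Arg334Trp	rs121909011
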