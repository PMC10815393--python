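# Allele spectrum of CF-causing CFTR variants in two local biocollections of
# genotyped CF patients (St. Petersburg includes adults; Yugra is children
# under 18). These regions lie inside the Northwestern and Ural federal
# districts respectively and are kept separate from the district-level table.
region	n	F508del_AF	F508del_AC	CFTRdele2,3(21kb)_AF	CFTRdele2,3(21kb)_AC	other_AF	other_AC
St.Petersburg	2412	0.59	2846	0.037	178	0.373	1799
Yugra region	54	0.398	43	0.046	5	0.556	60
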