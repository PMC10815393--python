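# Allele spectrum of CF-causing CFTR variants among registered CF patients
# (children under 18) per Russian federal district, as published from the
# national CF patient registry. The "Russian Federation" row is the national
# aggregate of the district rows. Counts are alleles among 2n CF chromosomes;
# some rows are internally rounded in the source and do not sum exactly to 2n.
region	n	F508del_AF	F508del_AC	CFTRdele2,3(21kb)_AF	CFTRdele2,3(21kb)_AC	other_AF	other_AC
Russian Federation	3292	0.5155	3400	0.0611	403	0.423	2793
Central Federal District	805	0.521	839	0.078	126	0.401	645
Northwestern Federal District	263	0.561	295	0.049	26	0.39	205
Southern Federal District	323	0.553	357	0.064	47	0.384	248
North Caucasian Federal District	170	0.214	73	0.016	5	0.771	262
Volga Federal District	566	0.504	571	0.052	59	0.444	502
Ural Federal District	245	0.538	264	0.048	24	0.412	202
Siberian Federal District	362	0.554	401	0.064	46	0.383	277
Far Eastern Federal District	146	0.536	157	0.069	20	0.394	115
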