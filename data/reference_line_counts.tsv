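# published de novo event tallies per line parent (tester row last)
line	n_individuals	duplication	deletion	her	aneuploid	total
ACSRsyn1	16	2	2	0	0	4
Bronowski	16	0	1	0	0	1
Daichousen	16	0	0	1	1	2
MarisHaplona	48	1	8	0	1	10
Surpass400	16	0	0	0	0	0
SvalofsGulle	16	1	0	0	1	2
Tribune	16	2	2	0	1	5
Topas	16	0	1	0	1	2
PAK85912	46	5	4	5	3	17
Zhongyou821	48	3	2	0	4	9
Rainbow	254	12	22	30	13	77
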