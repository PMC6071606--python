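# published reciprocal exchange events as (gained chromosome, lost chromosome,
# count). Pairings reproduce the per-chromosome gain/loss marginals and the
# documented pairings (A1/C1 17 events, A9 with C8 x3 and C9 x2, A2/C2);
# the A5->C4 entry balances the remaining marginals.
gain_chromosome	loss_chromosome	count
A1	C1	13
C1	A1	4
A2	C2	1
C2	A2	1
A3	C3	2
C3	A3	3
A4	C4	2
A5	C4	1
A5	C5	2
C5	A5	2
A9	C8	2
C8	A9	1
A9	C9	1
C9	A9	1
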