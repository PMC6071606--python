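# published de novo event tallies per chromosome.
# aneuploid_gain/aneuploid_loss split the aneuploid column; the per-chromosome
# allocation honors the published aggregates (13 additions vs 12 losses,
# 9 additions on the A genome incl. 3x A8, gains of A7/C6/C9 in named
# individuals) and is otherwise an arbitrary consistent assignment.
chromosome	duplication	deletion	her_gain	her_loss	aneuploid	aneuploid_gain	aneuploid_loss	total
A1	3	1	13	4	1	1	0	22
A2	3	6	1	1	4	2	2	15
A3	0	3	2	3	0	0	0	8
A4	1	1	2	0	1	0	1	5
A5	6	1	3	2	2	1	1	14
A6	1	2	0	0	0	0	0	3
A7	1	3	0	0	2	1	1	6
A8	0	1	0	0	3	3	0	4
A9	2	7	3	2	0	0	0	14
A10	0	2	0	0	1	1	0	3
C1	0	3	4	13	1	0	1	21
C2	2	2	1	1	5	1	4	11
C3	3	1	3	2	0	0	0	9
C4	0	0	0	3	0	0	0	3
C5	0	2	2	2	0	0	0	6
C6	1	2	0	0	1	1	0	4
C7	1	2	0	0	1	0	1	4
C8	2	2	1	2	2	1	1	9
C9	0	1	1	1	1	1	0	4
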