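protein_id	experiment	antibody	treatment	total_peptides	distinct_peptides
GhCESA1	1	target	blank	49	23
GhCESA1	1	target	treated	82	34
GhCESA1	2	target	blank	59	23
GhCESA1	2	target	treated	97	26
GhCESA1	3	target	blank	42	25
GhCESA1	3	target	treated	58	27
GhCESA2	1	target	blank	48	24
GhCESA2	1	target	treated	82	32
GhCESA2	2	target	blank	31	17
GhCESA2	2	target	treated	66	20
GhCESA2	3	target	blank	22	16
GhCESA2	3	target	treated	32	19
GhCESA7	1	target	blank	40	20
GhCESA7	1	target	treated	55	23
GhCESA7	2	target	blank	46	15
GhCESA7	2	target	treated	70	21
GhCESA7	3	target	blank	35	17
GhCESA7	3	target	treated	55	24
GhCESA8	1	target	blank	50	22
GhCESA8	1	target	treated	69	27
GhCESA8	2	target	blank	63	18
GhCESA8	2	target	treated	98	22
GhCESA8	3	target	blank	42	17
GhCESA8	3	target	treated	62	25
GhCALS	1	target	blank	3	3
GhCALS	1	target	treated	4	3
GhCALS	2	target	blank	1	1
GhCALS	2	target	treated	4	3
GhCALS	3	target	blank	1	1
GhCALS	3	target	treated	11	8
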