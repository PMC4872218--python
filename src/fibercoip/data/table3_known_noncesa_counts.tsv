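protein_id	experiment	antibody	treatment	total_peptides	distinct_peptides
alpha-tubulin 4	1	target	blank	20	10
alpha-tubulin 4	1	target	treated	22	10
alpha-tubulin 4	2	target	blank	14	6
alpha-tubulin 4	2	target	treated	14	7
alpha-tubulin 4	3	target	blank	0	0
alpha-tubulin 4	3	target	treated	12	9
beta-tubulin 3	1	target	blank	25	10
beta-tubulin 3	1	target	treated	23	10
beta-tubulin 3	2	target	blank	30	10
beta-tubulin 3	2	target	treated	19	8
beta-tubulin 3	3	target	blank	33	11
beta-tubulin 3	3	target	treated	0	0
beta-tubulin 7	1	target	blank	19	7
beta-tubulin 7	1	target	treated	23	8
beta-tubulin 7	2	target	blank	33	12
beta-tubulin 7	2	target	treated	20	8
beta-tubulin 7	3	target	blank	37	11
beta-tubulin 7	3	target	treated	32	12
endo-1,4-beta-glucanase (KOR)	1	target	blank	3	2
endo-1,4-beta-glucanase (KOR)	1	target	treated	2	2
endo-1,4-beta-glucanase (KOR)	2	target	blank	21	8
endo-1,4-beta-glucanase (KOR)	2	target	treated	14	5
endo-1,4-beta-glucanase (KOR)	3	target	blank	23	12
endo-1,4-beta-glucanase (KOR)	3	target	treated	25	13
sucrose synthase 1	1	target	blank	6	3
sucrose synthase 1	1	target	treated	4	2
sucrose synthase 1	2	target	blank	10	6
sucrose synthase 1	2	target	treated	9	5
sucrose synthase 1	3	target	blank	20	13
sucrose synthase 1	3	target	treated	16	12
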