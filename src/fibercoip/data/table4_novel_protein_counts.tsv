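protein_id	experiment	antibody	treatment	total_peptides	distinct_peptides
Phenylcoumaran benzylic ether reductase-like protein	1	target	blank	3	2
Phenylcoumaran benzylic ether reductase-like protein	1	target	treated	8	5
Phenylcoumaran benzylic ether reductase-like protein	2	target	blank	2	1
Phenylcoumaran benzylic ether reductase-like protein	2	target	treated	3	2
Phenylcoumaran benzylic ether reductase-like protein	3	target	blank	3	3
Phenylcoumaran benzylic ether reductase-like protein	3	target	treated	6	5
vacuolar H+-ATPase catalytic subunit	1	target	blank	8	4
vacuolar H+-ATPase catalytic subunit	1	target	treated	16	9
vacuolar H+-ATPase catalytic subunit	2	target	blank	0	0
vacuolar H+-ATPase catalytic subunit	2	target	treated	4	3
vacuolar H+-ATPase catalytic subunit	3	target	blank	11	9
vacuolar H+-ATPase catalytic subunit	3	target	treated	15	8
glyceraldehyde-3-phosphate dehydrogenase C subunit	1	target	blank	48	18
glyceraldehyde-3-phosphate dehydrogenase C subunit	1	target	treated	44	18
glyceraldehyde-3-phosphate dehydrogenase C subunit	2	target	blank	37	12
glyceraldehyde-3-phosphate dehydrogenase C subunit	2	target	treated	17	8
glyceraldehyde-3-phosphate dehydrogenase C subunit	3	target	blank	16	12
glyceraldehyde-3-phosphate dehydrogenase C subunit	3	target	treated	16	12
fasciclin-like arabinogalactan protein	1	target	blank	2	1
fasciclin-like arabinogalactan protein	1	target	treated	2	2
fasciclin-like arabinogalactan protein	2	target	blank	2	1
fasciclin-like arabinogalactan protein	2	target	treated	7	4
fasciclin-like arabinogalactan protein	3	target	blank	5	4
fasciclin-like arabinogalactan protein	3	target	treated	5	5
UDP-glucuronic acid decarboxylase 2	1	target	blank	15	7
UDP-glucuronic acid decarboxylase 2	1	target	treated	20	8
UDP-glucuronic acid decarboxylase 2	2	target	blank	8	5
UDP-glucuronic acid decarboxylase 2	2	target	treated	0	0
UDP-glucuronic acid decarboxylase 2	3	target	blank	10	6
UDP-glucuronic acid decarboxylase 2	3	target	treated	21	11
tonoplast intrinsic protein	1	target	blank	0	0
tonoplast intrinsic protein	1	target	treated	1	1
tonoplast intrinsic protein	2	target	blank	2	1
tonoplast intrinsic protein	2	target	treated	2	1
tonoplast intrinsic protein	3	target	blank	1	1
tonoplast intrinsic protein	3	target	treated	1	1
ubiquitin extension protein	1	target	blank	8	5
ubiquitin extension protein	1	target	treated	12	5
ubiquitin extension protein	2	target	blank	5	3
ubiquitin extension protein	2	target	treated	7	3
ubiquitin extension protein	3	target	blank	9	4
ubiquitin extension protein	3	target	treated	10	4
3-ketoacyl-CoA reductase 1	1	target	blank	5	3
3-ketoacyl-CoA reductase 1	1	target	treated	19	10
3-ketoacyl-CoA reductase 1	2	target	blank	1	1
3-ketoacyl-CoA reductase 1	2	target	treated	5	3
3-ketoacyl-CoA reductase 1	3	target	blank	6	3
3-ketoacyl-CoA reductase 1	3	target	treated	8	5
plasma membrane H+-ATPase, partial	1	target	blank	2	1
plasma membrane H+-ATPase, partial	1	target	treated	3	2
plasma membrane H+-ATPase, partial	2	target	blank	0	0
plasma membrane H+-ATPase, partial	2	target	treated	2	1
plasma membrane H+-ATPase, partial	3	target	blank	2	2
plasma membrane H+-ATPase, partial	3	target	treated	2	2
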