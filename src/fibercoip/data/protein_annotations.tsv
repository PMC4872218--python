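protein_id	category	accession	tm_domains	function
GhCESA1	cesa			cellulose synthase catalytic subunit, secondary cell wall
GhCESA2	cesa			cellulose synthase catalytic subunit, secondary cell wall
GhCESA7	cesa			cellulose synthase catalytic subunit, secondary cell wall
GhCESA8	cesa			cellulose synthase catalytic subunit, secondary cell wall
GhCALS	cals			callose synthase, beta-1,3-glucan synthesis
alpha-tubulin 4	known_noncesa	gi|37529490	0	Cytoskeleton, GTPase activity, guidance of cellulose deposition
beta-tubulin 3	known_noncesa	gi|223453022	0	Cytoskeleton, GTPase activity, protein binding, guidance of cellulose deposition
beta-tubulin 7	known_noncesa	gi|37529498	0	Cytoskeleton, GTPase activity, protein binding, guidance of cellulose deposition
endo-1,4-beta-glucanase (KOR)	known_noncesa	gi|32454474	1	cellulase activity, cellulose biosynthesis
sucrose synthase 1	known_noncesa	gi|258489633	0	UDP-glycosyltransferase activity, cellulose biosynthesis
Phenylcoumaran benzylic ether reductase-like protein	cesa_associated	gi|124488476	0	isoflavone reductase
vacuolar H+-ATPase catalytic subunit	cesa_associated	gi|167313	0	cytoskeleton, ATP binding, hydrolase activity
glyceraldehyde-3-phosphate dehydrogenase C subunit	cesa_associated	gi|211906518	0	NAD binding, NADP binding, oxidoreductase activity
fasciclin-like arabinogalactan protein	cesa_associated	gi|606942	1	cell wall biogenesis, acetyl-CoA metabolic process
UDP-glucuronic acid decarboxylase 2	cesa_associated	gi|213950353	1	UDP-xylose metabolic, UDP-glucuronate decarboxylase activity
tonoplast intrinsic protein	cesa_associated	gi|227434194	6	water channel, facilitate transport of urea and hydrogen peroxide
ubiquitin extension protein	cals_associated	gi|73761683	0	structural constituent of ribosome, ubiquitin-dependent protein catabolic process
3-ketoacyl-CoA reductase 1	cals_associated	gi|62956018	1	acetoacetyl-CoA reductase, ketoreductase, oxidoreductase
plasma membrane H+-ATPase, partial	cals_associated	gi|2911803	9	ATPase activity, cation transport
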