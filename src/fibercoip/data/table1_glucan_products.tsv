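method	glucan	cpm_mean	cpm_sd	nmol_mean	nmol_sd
sucrose_density	b14	5670	190	50.0	2.0
sucrose_density	b13	12900	1000	113	9.0
sedimentation_velocity	b14	10100	400	89.0	3.0
sedimentation_velocity	b13	22200	1500	195	14
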