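# Manifest of the 21 identified sirolimus metabolites (five structural
# classes). Each row is rendered to a noise-free MS/MS spectrum by
# synthetic_data.simulate_spectrum for the batch fixtures. truth syntax:
# "OH@site" / "DM@site" joined by "+"; ambiguous pairs "23/24", "45/46";
# the unresolved piperidine ring is "pip". The four hydroxy-piperidine
# chromatographic isomers (a-d) share one MS truth but count as distinct
# entries, as the published metabolite table does. reported_sites is the
# site string the published analysis assigns (MS evidence only; the 45- vs
# 46- and 23- vs 24- preference comes from simulation, not MS).
id	name	truth	class_expected	reported_sites
M01	46-hydroxy SRL	OH@45/46	hydroxylated	45/46
M02	45-hydroxy SRL	OH@45/46	hydroxylated	45/46
M03	23/24-hydroxy SRL	OH@23/24	hydroxylated	23/24
M04	12-hydroxy SRL	OH@12	hydroxylated	12
M05	25-hydroxy SRL	OH@25	hydroxylated	25
M06	11-hydroxy SRL	OH@11	hydroxylated	11
M07	hydroxy-piperidine SRL (a)	OH@pip	hydroxylated	pip
M08	hydroxy-piperidine SRL (b)	OH@pip	hydroxylated	pip
M09	hydroxy-piperidine SRL (c)	OH@pip	hydroxylated	pip
M10	hydroxy-piperidine SRL (d)	OH@pip	hydroxylated	pip
M11	14-hydroxy SRL	OH@14	hydroxylated	14
M12	49-hydroxy SRL	OH@49	hydroxylated	49
M13	12,23/24-dihydroxy SRL	OH@12+OH@23/24	di-hydroxylated	12+23/24
M14	16-O-desmethyl SRL	DM@16	O-demethylated	16
M15	27-O-desmethyl SRL	DM@27	O-demethylated	27
M16	39-O-desmethyl SRL	DM@39	O-demethylated	39
M17	27,39-O-didesmethyl SRL	DM@27+DM@39	didemethylated	27+39
M18	16,39-O-didesmethyl SRL	DM@16+DM@39	didemethylated	16+39
M19	hydroxy-piperidine,39-O-desmethyl SRL	OH@pip+DM@39	hydroxylated/demethylated	pip+39
M20	12-hydroxy,39-O-desmethyl SRL	OH@12+DM@39	hydroxylated/demethylated	12+39
M21	11-hydroxy,16-O-desmethyl SRL	OH@11+DM@16	hydroxylated/demethylated	11+16
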