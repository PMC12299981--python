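# Sirolimus sodiated fragment library (IUPAC numbering).
# kind: precursor | alpha_cleavage | hydroxylation_diagnostic
# coverage: comma list of carbon positions; ranges "a-b"; token "pip" = piperidine C3-C6.
# m/z stored at 6 dp. The 4-dp rounding of every alpha-cleavage/precursor mass matches
# the published exact-mass table; the extra digits are a reconstruction chosen so that
# shifted metabolite ions also reproduce the published 4-dp values (the deposited
# appendix with fragment formulas is not public). Coverage sets are likewise a
# synthetic reconstruction constrained by all main-text anchors: K covers C17-C49,
# C51, C52 and excludes C16/C11/C12/C14/piperidine; C and D cover C39 and exclude
# C27; G and O cover C23/C24; Q covers the piperidine ring.
# Note: the 27-O-desmethyl molecular ion is printed once as 922.5887 in the source
# text; every other demethylated ion is 922.5287 and the shift arithmetic gives
# 922.5287 (treated as a typo, flagged here rather than silently corrected).
label	kind	mz	parent	coverage	diagnostic_site
SRL	precursor	936.544362	-	1,2,pip,7-52	-
A	alpha_cleavage	731.449300	SRL	10-52	-
B	alpha_cleavage	763.475600	SRL	1,2,pip,7-36,45-48,50,51	-
E	alpha_cleavage	703.454400	B	1,2,pip,7-33,45-48,50,51	-
M	alpha_cleavage	582.303700	E	1,2,pip,7-16,47,50	-
N	alpha_cleavage	453.224800	M	1,2,pip,7-16,50	-
H	alpha_cleavage	485.251000	M	7-16,47,50	-
F	alpha_cleavage	399.250600	H	11-16,47,50	-
J	alpha_cleavage	409.234900	N	1,2,pip,7-15	-
P	alpha_cleavage	381.240000	J	1,2,pip,7-14	-
Q	alpha_cleavage	320.110500	P	1,2,pip,7-10	-
K	alpha_cleavage	607.396920	A	17-49,51,52	-
R	alpha_cleavage	413.266200	K	27-36,49,51	-
C	alpha_cleavage	642.324870	A	28-44,49,52	-
D	alpha_cleavage	345.203620	C	33-44,49,52	-
G	alpha_cleavage	614.330020	A	17-27,45,46,48,51	-
O	alpha_cleavage	441.261100	G	17-26,45,46,48	-
I	alpha_cleavage	459.271700	G	18-27,45,46,51	-
L	alpha_cleavage	397.234900	O	18-26,45,46	-
OH11-diag	hydroxylation_diagnostic	723.480600	-	1,2,pip,7-10,12-16,47,50	11
OH12-diag-a	hydroxylation_diagnostic	711.444200	-	10,11,13-44,47,48,50,51,52	12
OH12-diag-b	hydroxylation_diagnostic	389.229300	-	10,11,13-26,45,46	12
OH12-diag-c	hydroxylation_diagnostic	357.203100	-	10,11,13-15	12
OH14-diag	hydroxylation_diagnostic	612.313300	-	7-13,15,16,47,50	14
OH25-diag-a	hydroxylation_diagnostic	447.271800	-	17-24,26,27,45,46,48,51	25
OH25-diag-b	hydroxylation_diagnostic	327.192200	-	17-24,26	25
OH49-diag	hydroxylation_diagnostic	361.197800	-	33-44,52	49
OHpip-diag	hydroxylation_diagnostic	336.105000	-	1,2,7-10	pip
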