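# Published apparent Michaelis-Menten parameters (n = 4) for metabolite
# formation by pooled human liver microsomes, with printed CL_int and the
# printed 95% CIs. clint_printed kept verbatim (12-hydroxy is printed at 1 dp).
metabolite	vmax	km	clint_printed	vmax_ci	km_ci
23/24-hydroxy	2.221	20.82	0.11	1.8-2.8	11.35-38.27
12-hydroxy	4.264	7.211	0.6	3.674-4.955	3.4-13.01
11-hydroxy	6.203	9.577	0.65	5.673-6.799	6.6-13.43
pip-hydroxy	2.781	13.15	0.21	2.350-3.333	7.1-23.14
16-desmethyl	1.828	24.37	0.08	1.452-2.393	12.20-50.43
39-desmethyl	9.647	14.95	0.65	8.692-10.76	10.39-21.51
27-desmethyl	0.552	9.647	0.06	0.47-0.65	8.7-10.76
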