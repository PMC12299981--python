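# Published theoretical vs measured exact masses (sodiated ions) of the
# sirolimus fragments used for metabolite identification, with the printed
# 1-dp ppm error. Row O prints 0.5 ppm but |441.2610-441.2611|/441.2611e-6
# computes to 0.2 at 1 dp; the printed value is kept here verbatim.
label	theoretical	measured	ppm_printed
SRL	936.5444	936.5444	0.0
A	731.4493	731.4491	0.3
B	763.4756	763.4756	0.0
C	642.3249	642.3250	0.2
D	345.2036	345.2038	0.6
E	703.4544	703.4547	0.4
F	399.2506	399.2508	0.5
G	614.3300	614.3298	0.3
H	485.2510	485.2511	0.2
I	459.2717	459.2718	0.2
J	409.2349	409.2350	0.2
K	607.3969	607.3969	0.0
L	397.2349	397.2363	3.5
M	582.3037	582.3035	0.3
N	453.2248	453.2247	0.2
O	441.2611	441.2610	0.5
P	381.2400	381.2401	0.3
Q	320.1105	320.1104	0.3
R	413.2662	413.2662	0.0
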