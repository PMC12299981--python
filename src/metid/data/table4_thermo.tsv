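# Published DFT thermodynamic-cycle terms for O-demethylation (kcal/mol):
# methyl abstraction (MO-CH3 -> MO + CH3), hydrogenation (MO + H -> MOH),
# and the printed overall dG. The C27 row prints -12.71 while
# 78.12 + (-90.82) = -12.70; the printed value is kept verbatim and the
# package computes the sum.
site	dg_demethylation	dg_hydrogenation	dg_overall_printed
C16	84.43	-108.48	-24.05
C27	78.12	-90.82	-12.71
C39	85.62	-107.51	-21.89
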