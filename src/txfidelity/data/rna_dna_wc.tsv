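# RNA/DNA hybrid Watson-Crick nearest-neighbor dG37 (Sugimoto 1995), RNA 5'->3'
# duplex_class	top_5to3	bottom_3to5	dG37_kcal_per_mol
RNA_DNA_WC	AA	TT	-1.00
RNA_DNA_WC	AC	TG	-2.10
RNA_DNA_WC	AG	TC	-1.80
RNA_DNA_WC	AU	TA	-0.90
RNA_DNA_WC	CA	GT	-0.90
RNA_DNA_WC	CC	GG	-2.10
RNA_DNA_WC	CG	GC	-1.70
RNA_DNA_WC	CU	GA	-0.90
RNA_DNA_WC	GA	CT	-1.30
RNA_DNA_WC	GC	CG	-2.70
RNA_DNA_WC	GG	CC	-2.90
RNA_DNA_WC	GU	CA	-1.10
RNA_DNA_WC	UA	AT	-0.60
RNA_DNA_WC	UC	AG	-1.50
RNA_DNA_WC	UG	AC	-1.60
RNA_DNA_WC	UU	AA	-0.20
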