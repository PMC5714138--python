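# SYNTHETIC RNA/DNA mismatch nearest-neighbor dG37 stand-in table.
# Constructed as the Watson-Crick step value plus a context-varying
# destabilization penalty with single-step mean +0.90 kcal/mol across
# contexts (the measured average WC-vs-terminal-mismatch hybrid difference).
# Covers rA.dA, rC.dC, rG.dG, rU.dT in all neighbor contexts and both slots.
# duplex_class	top_5to3	bottom_3to5	dG37_kcal_per_mol
RNA_DNA_MISMATCH	AA	AT	0.05
RNA_DNA_MISMATCH	AA	TA	-0.25
RNA_DNA_MISMATCH	AC	AG	-0.50
RNA_DNA_MISMATCH	CA	GA	0.10
RNA_DNA_MISMATCH	AG	AC	-0.70
RNA_DNA_MISMATCH	GA	CA	-0.20
RNA_DNA_MISMATCH	AU	AA	0.45
RNA_DNA_MISMATCH	UA	AA	0.45
RNA_DNA_MISMATCH	CA	CT	-0.30
RNA_DNA_MISMATCH	AC	TC	-0.80
RNA_DNA_MISMATCH	CC	CG	-1.35
RNA_DNA_MISMATCH	CC	GC	-0.35
RNA_DNA_MISMATCH	CG	CC	-1.65
RNA_DNA_MISMATCH	GC	CC	-1.65
RNA_DNA_MISMATCH	CU	CA	-0.10
RNA_DNA_MISMATCH	UC	AC	-0.60
RNA_DNA_MISMATCH	GA	GT	-0.25
RNA_DNA_MISMATCH	AG	TG	-1.45
RNA_DNA_MISMATCH	GC	GG	-1.10
RNA_DNA_MISMATCH	CG	GG	-1.10
RNA_DNA_MISMATCH	GG	GC	-0.80
RNA_DNA_MISMATCH	GG	CG	-1.80
RNA_DNA_MISMATCH	GU	GA	-0.25
RNA_DNA_MISMATCH	UG	AG	-0.85
RNA_DNA_MISMATCH	UA	TT	-0.30
RNA_DNA_MISMATCH	AU	TT	-0.30
RNA_DNA_MISMATCH	UC	TG	-1.05
RNA_DNA_MISMATCH	CU	GT	0.15
RNA_DNA_MISMATCH	UG	TC	-0.85
RNA_DNA_MISMATCH	GU	CT	-0.35
RNA_DNA_MISMATCH	UU	TA	-0.20
RNA_DNA_MISMATCH	UU	AT	0.10
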