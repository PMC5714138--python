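# DNA/DNA nearest-neighbor dG37 (SantaLucia 1998 unified), coding strand 5'->3'
# duplex_class	top_5to3	bottom_3to5	dG37_kcal_per_mol
DNA_DNA	AA	TT	-1.00
DNA_DNA	AC	TG	-1.44
DNA_DNA	AG	TC	-1.28
DNA_DNA	AT	TA	-0.88
DNA_DNA	CA	GT	-1.45
DNA_DNA	CC	GG	-1.84
DNA_DNA	CG	GC	-2.17
DNA_DNA	CT	GA	-1.28
DNA_DNA	GA	CT	-1.30
DNA_DNA	GC	CG	-2.24
DNA_DNA	GG	CC	-1.84
DNA_DNA	GT	CA	-1.44
DNA_DNA	TA	AT	-0.58
DNA_DNA	TC	AG	-1.30
DNA_DNA	TG	AC	-1.45
DNA_DNA	TT	AA	-1.00
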