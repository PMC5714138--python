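# Default parameter set for the two-step proofreading transcription model.
#
# Free-energy barriers are per reaction type (kcal/mol) and enter the Eyring
# expression k = k_pre * exp(-(dG_barrier + max(dG_to - dG_from, 0)) / (R*T)).
# The association barrier is calibrated so that a 5.5-kb template transcribes
# in about 60 s at the default NTP pool (the in vivo rRNA-operon time scale).
constants:
  R: 1.987e-3        # kcal/(mol*K)
  T: 310.15          # K
  k_pre: 1.0e+6      # 1/s (and 1/(uM*s) for the bimolecular association step)

geometry:
  melted_dna_bp: 12
  hybrid_bp: 9

barriers:              # kcal/mol
  translocation: 1.5   # PRE <-> POST
  backstep: 3.1        # PRE <-> BACK
  ntp_association: 4.1 # POST -> POST.NTP, per uM
  ntp_dissociation: 0.7
  bond_formation: 4.3  # POST.NTP -> PRE(i+1)
  cleavage: 7.5        # BACK -> POST(i-2), releases a dinucleotide

polymerase_effect:
  factor: 50.0                 # mismatch discrimination in bond formation / cleavage
  back_stabilization_ddG: 1.0  # kcal/mol, BACK stabilized when last/penultimate is a mismatch

ntp_pool:              # uM
  ATP: 3000.0
  CTP: 500.0
  GTP: 1000.0
  UTP: 1000.0

dG_pol: 0.0            # kcal/mol, constant polymerase term in dG_state

nn_tables:
  dna_dna: default
  rna_dna_wc: default
  rna_dna_mismatch: default
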