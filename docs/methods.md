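# Methods

## The model

`txfidelity` computes the sequence-dependent accuracy of transcript
elongation by a proofreading RNA polymerase. Each elongation state E_i
(transcript length i) comprises four sub-states — pre-translocated (PRE),
post-translocated (POST), substrate-bound (POST·NTP) and backstepped
(BACK) — connected by eight rate constants: backstepping k1/q1,
translocation k2/q2, NTP association k3·[NTP] and dissociation q3,
phosphodiester bond formation kc, and transcript cleavage qc. Cleavage from
BACK always removes the 3'-terminal dinucleotide and deposits the complex in
the post-translocated register of E_{i-2}, so every position is scrutinized
twice: once while the candidate base is 3'-terminal (first proofreading
step, F1) and once while it is penultimate (second step, F2).

### Free energies

The free energy of every sub-state is the nearest-neighbor energy of its
transcription bubble (Watson–Crick DNA/DNA and RNA/DNA dinucleotide-step
dG37 values, plus mismatch steps where the transcript carries an error):

    dG_state = dG_DNA/DNA + dG_RNA/DNA + dG_pol

with dG_DNA/DNA the cost of holding the 12-bp melted DNA window open,
dG_RNA/DNA the formation energy of the 9-bp RNA/DNA hybrid, and dG_pol a
constant that cancels from every rate (default 0). Window registers: PRE
pairs transcript positions [i−8, i]; POST [i−7, i] with the active site at
i+1 exposed; POST·NTP adds the candidate·template pair at i+1; BACK pairs
[i−9, i−1] with nucleotide i extruded into the backtrack pocket. These
registers reproduce the defining asymmetry of the two proofreading steps: a
3'-terminal mismatch appears in one PRE hybrid step and in none of BACK's,
while a penultimate mismatch appears in two PRE steps and one BACK step.
Positions whose full window does not fit (the first hybrid-length+1 and the
last melted−hybrid+1 positions) are excluded from profiles and reported.

### Rates

Rates follow the Eyring form k = k_pre·exp(−(ΔG‡ + max(ΔG_to − ΔG_from,
0))/RT), one fixed barrier ΔG‡ per reaction type, so each translocation pair
obeys detailed balance exactly. Bond formation and cleavage are barrier-only
and instead carry the uniform *polymerase effect* (factor 50): bond
formation is 50-fold slower when the active-site pair of base pairs contains
a mismatch, cleavage 50-fold faster when the cleavable 3' dinucleotide does.
NTP association is barrier-only and identity-blind (discrimination on
binding enters through q3, whose uphill cost is the stability of the newest
hybrid step). A tracked mismatch at the last or penultimate position
additionally stabilizes BACK by a fixed ddG (default 1.0 kcal/mol),
reflecting the greater accessibility of the backtrack pocket to
misincorporated 3' ends.

The model tracks at most one outstanding mismatch and forbids consecutive
mismatches; a mismatch three or more positions behind the 3' end is treated
as energetically silent (its steps revert to Watson–Crick values). Cleavage
of a dinucleotide containing the tracked mismatch clears it.

### Selection factors

Initial selection I, and the two proofreading factors F1/F2 built from the
compound cleavage:elongation ratio s/k of one elongation state,

    s/k = (k1/k2) · (1 + q2/(k3[NTP]) · (1 + q3/kc)) / (1 + q1/qc),

are evaluated per position and competitor; the closed form is identical to
the splitting probability of the four-sub-state absorbing chain (verified to
1e-10 in the tests). The normalized accuracy is A = I·F1·F2, the total
accuracy weights the three competing NTPs by concentration, and
Err = 1/(1 + A_tot). An unweighted variant sets all concentrations equal.

### Revisits

Cleavage at E_{j} returns the polymerase to E_{j-2}, granting the then-last
and penultimate nucleotides one extra proofreading round each. Expected
visit counts solve N_j = N_{j-1}(1−p_{j-1}) + N_{j+2} p_{j+2} with p_j the
per-visit cleavage probability of E_j computed from *cognate* rates —
error-conditioned revisit traffic is deliberately omitted as a
second-order effect, and the simulator comparison is therefore made in a
regime without misincorporation. Amplification uses fractional exponents,
A_amp = I·F1^(1+RV_last)·F2^(1+RV_penult), because RV is an expectation:
each expected extra round multiplies the accuracy by the geometric mean of
one more selection factor. The first two modeled cycles cannot
backstep-cleave (they would leave the modeled region), and the last two
positions have no downstream cleavage state, so RV = 0 there.

### Transcription time

Total transcription time is the mean first-passage time of the full
sub-state chain — including non-cognate branches, the 3'-mismatch and
penultimate-mismatch channels, and cleavage re-entry into POST of E_{i-2} —
solved sparsely from Q t = −1. `step1_only` mode removes the
mismatch-dependent modifications of the cycle following a misincorporation,
isolating the (small, positive) time cost of the second proofreading step.
Edge positions outside the valid window range are bridged at the interior's
mean per-position pace.

### Simulator

The direct-method Gillespie simulator executes the same machine with exact
per-position bookkeeping (misincorporations flagged on the transcript, one
RNG stream per trajectory hashed from the master seed). It is the package's
independent oracle: completion times, final-transcript error frequencies and
revisit tallies are required (in the test suite) to match the analytic
calculations within three standard errors.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| T | 310.15 | K | temperature (NN tables are 37 °C standards) |
| R | 1.987e-3 | kcal/(mol·K) | gas constant |
| k_pre | 1e6 | 1/s | Eyring pre-factor (per µM for association) |
| translocation ΔG‡ | 1.5 | kcal/mol | PRE↔POST |
| backstep ΔG‡ | 3.1 | kcal/mol | PRE↔BACK |
| ntp_association ΔG‡ | 4.1 | kcal/mol | POST→POST·NTP (per µM) |
| ntp_dissociation ΔG‡ | 0.7 | kcal/mol | POST·NTP→POST |
| bond_formation ΔG‡ | 4.3 | kcal/mol | catalysis (kc ≈ 930/s) |
| cleavage ΔG‡ | 7.5 | kcal/mol | BACK→cleaved (qc ≈ 5/s) |
| polymerase factor | 50 | – | mismatch discrimination in kc and qc |
| back_stabilization_ddG | 1.0 | kcal/mol | BACK with a last/penultimate mismatch |
| NTP pool | A 3000, C 500, G 1000, U 1000 | µM | cellular concentrations |
| bubble | 12 bp melted, 9 bp hybrid | – | geometry (hybrid configurable to 8) |

The barrier set was calibrated once, before any acceptance measurement, to
the in-vivo time scale of ribosomal-operon transcription: ~60 s for a
5.5-kb template at the default pool (≈92 nt/s), with NTP binding operating
near equilibrium (q3 ≫ kc at most positions) so that initial selection
approaches its thermodynamic ceiling, and with backstepping frequent enough
that a 3'-mismatch is cleaved with high probability while cognate cleavage
stays rare (~0.2–0.3% of positions per pass). The factor-50 polymerase
effect is implemented as a symmetric ratio (kc ÷ 50 for mismatched bond
formation, qc × 50 for mismatched cleavage); only the ratio is observable in
the selection formulas.

## Nearest-neighbor tables

DNA/DNA steps are the unified dG37 set (SantaLucia 1998); RNA/DNA
Watson–Crick steps are the hybrid dG37 set (Sugimoto 1995). The published
RNA/DNA single-mismatch set covers only rA·dA, rC·dC, rG·dG and rU·dT, one
identity per template base; all twelve mismatches are therefore grouped by
template base and assigned that template's published identity (the lookup
records every such substitution). The shipped mismatch table itself
(`rna_dna_mismatch_synthetic.tsv`) is a **synthetic stand-in**: each entry
is the corresponding Watson–Crick step value plus a destabilization penalty
that varies by template base and neighbor (0.65–1.35 kcal/mol) with a
single-step mean of exactly +0.90 kcal/mol — the measured average
free-energy difference between a correct and a terminally mismatched
RNA/DNA hybrid, which fixes the mean Pauling discrimination at 4.3. Any
measured table in the same TSV format can be dropped in via the parameter
file. No terminal/dangling-end or initiation corrections are applied, and no
salt or temperature extrapolation is performed.

## What the synthetic data show — and what they do not

Random templates (uniform or GC-biased) and the synthetic mismatch table
exercise every code path: the sequence-dependent spread of I, F1, F2 over
several orders of magnitude, the log-scale (near log-normal) error and
revisit distributions, the dominance of the first proofreading step and its
quenching at high NTP concentration, and the small positive time cost of the
second step. They do not reproduce the numerical error landscape of a real
operon: the true mismatch energies are more irregular than the constructed
penalties, real templates have correlated base composition, and pause-prone
motifs are only as frequent as chance places them. Passing tests therefore
establish internal correctness (formulas ≡ Markov solves ≡ stochastic
simulation) and qualitative behavior, not organism-level error rates.

## Numerical choices

* Closed forms are used wherever exact (selection factors); linear systems
  are solved sparsely (SuperLU) for visits and first-passage times; the
  revisit amplification is evaluated in log space to survive strongly
  amplified pause-site positions (error floored at 1e-300).
* The Eyring `max(ΔG, 0)` convention makes downhill rates barrier-only;
  ties (equal ground states) need no special handling.
* Profiles are computed from vectorized cumulative sums of step energies;
  the scalar per-position construction is kept as the reference
  implementation and the two are asserted identical.
* Degenerate inputs fail loudly: non-DNA characters report their position,
  templates shorter than the bubble span are rejected, missing Watson–Crick
  steps mark a corrupt table, and any per-visit cleavage probability of 1
  (a polymerase that never finishes) is an error.

## Known limitations

Single-step backtracking only (no long backtracks, no GreA/GreB kinetics),
no initiation or termination, no force dependence, no secondary structure of
the nascent RNA, uniform polymerase effect across base identities, and
mismatches deeper than the penultimate position are energetically silent.
The revisit recursion ignores error-conditioned traffic (second order at
realistic error rates, visible only in the synthetic high-error regime).
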