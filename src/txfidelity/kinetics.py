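"""Sub-state rate constants of the nucleotide addition cycle.

Each elongation state E_i (transcript length i) has four sub-states
(PRE, POST, POST.NTP, BACK) connected by eight rate constants:

    k1: PRE -> BACK      q1: BACK -> PRE      (backstepping)
    k2: PRE -> POST      q2: POST -> PRE      (translocation)
    k3*[NTP]: POST -> POST.NTP   q3: POST.NTP -> POST  (substrate binding)
    kc: POST.NTP -> PRE of E_{i+1}            (phosphodiester bond)
    qc: BACK -> POST of E_{i-2}               (dinucleotide cleavage)

Rates follow the Eyring form with a fixed barrier per reaction type plus the
ground-state free-energy difference when the reaction is uphill, so detailed
balance k/q = exp(-ddG/RT) holds for every translocation pair. Sequence
dependence enters exclusively through the bubble free energies; bond
formation and cleavage are barrier-only and carry the mismatch-discriminating
polymerase effect instead. NTP association is barrier-only by construction
(binding is stabilizing), so discrimination on binding enters via q3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import BarrierSet, ModelParams
from .thermo import (PositionOutOfRange, Substate, build_bubble_state,
                     encode_dna, lookup_step_dG, DinucStep, DuplexClass,
                     rna_complement, template_mismatch_partner, transcribe)

# channel codes shared with the simulator and the master equation
CH_CLEAN, CH_MM_LAST, CH_MM_PENULT = 0, 1, 2


def eyring_rate(barrier: float, dG_from: float, dG_to: float,
                barriers: BarrierSet) -> float:
    """k = k_pre * exp(-(barrier + max(dG_to - dG_from, 0)) / (R*T)).

    The transition state sits at the fixed reaction barrier above the higher
    of the two ground states, so uphill reactions pay the ground-state
    difference on top of the barrier and downhill ones do not.
    """
    if barrier < 0:
        raise ValueError("barrier must be >= 0")
    uphill = max(dG_to - dG_from, 0.0)
    return barriers.k_pre * np.exp(-(barrier + uphill) / barriers.RT)


@dataclass(frozen=True)
class StateRateSet:
    """The eight sub-state rate constants of one elongation cycle E_i -> E_{i+1}.

    ``k3_ntp`` is the pseudo-first-order association rate k3*[NTP] of the
    tracked candidate. ``prior_mismatch_offset`` is None (all-cognate
    context), 0 (mismatch at the 3' nucleotide i) or 1 (at i-1).
    """

    k1: float
    q1: float
    k2: float
    q2: float
    k3_ntp: float
    q3: float
    kc: float
    qc: float
    position: int = -1
    candidate_is_cognate: bool = True
    prior_mismatch_offset: int | None = None

    def __post_init__(self):
        for name in ("k1", "q1", "k2", "q2", "k3_ntp", "q3", "kc", "qc"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"rate {name} must be positive and finite, got {v}")


def apply_polymerase_effect(rates: StateRateSet, newest_pair_mismatch: bool,
                            cleavable_mismatch: bool, factor: float) -> StateRateSet:
    """Apply the uniform mismatch-discriminating polymerase effect.

    Bond formation is slowed by ``factor`` when the active-site pair of base
    pairs (last incorporated + incoming) contains a mismatch; cleavage is
    accelerated by ``factor`` when the cleavable 3' dinucleotide contains one.
    All-cognate contexts are untouched, and only kc/qc are ever modified.
    """
    if factor < 1:
        raise ValueError("polymerase-effect factor must be >= 1")
    kc = rates.kc / factor if newest_pair_mismatch else rates.kc
    qc = rates.qc * factor if cleavable_mismatch else rates.qc
    return replace(rates, kc=kc, qc=qc)


def build_rate_set(coding_seq: str, i: int, params: ModelParams,
                   candidate: str | None = None,
                   prior_mismatch_offset: int | None = None) -> StateRateSet:
    """All eight rate constants of cycle E_i (incorporating position i+1).

    ``candidate`` is the RNA base probed at i+1 (None = cognate);
    ``prior_mismatch_offset`` marks an already-incorporated mismatch at the
    3' end (0) or penultimate position (1). The BACK state is additionally
    stabilized by the configured ddG when such a mismatch is present.
    """
    b, pe, geom, tables = params.barriers, params.pe, params.geometry, params.tables
    rna = transcribe(coding_seq.upper())
    cognate_next = rna[i]  # RNA base at position i+1 (0-based index i)
    cand = cognate_next if candidate is None else candidate
    cand_mismatch = cand != cognate_next
    if cand_mismatch and prior_mismatch_offset == 0:
        raise ValueError("two consecutive mismatches are not modeled")

    offs = frozenset() if prior_mismatch_offset is None else frozenset({prior_mismatch_offset})
    kwargs = dict(tables=tables, geom=geom, dG_pol=params.dG_pol)
    pre = build_bubble_state(coding_seq, i, Substate.PRE, mismatch_offsets=offs, **kwargs)
    post = build_bubble_state(coding_seq, i, Substate.POST, mismatch_offsets=offs, **kwargs)
    back = build_bubble_state(coding_seq, i, Substate.BACK, mismatch_offsets=offs, **kwargs)
    ntp = build_bubble_state(coding_seq, i, Substate.POST_NTP, candidate=cand,
                             mismatch_offsets=offs, **kwargs)

    g_back = back.dG_state
    if prior_mismatch_offset in (0, 1):
        g_back -= pe.back_stabilization_ddG

    k1 = eyring_rate(b.dG_ddag["backstep"], pre.dG_state, g_back, b)
    q1 = eyring_rate(b.dG_ddag["backstep"], g_back, pre.dG_state, b)
    k2 = eyring_rate(b.dG_ddag["translocation"], pre.dG_state, post.dG_state, b)
    q2 = eyring_rate(b.dG_ddag["translocation"], post.dG_state, pre.dG_state, b)
    # association is identity-independent: barrier-only, scaled by [NTP]
    k3 = b.k_pre * np.exp(-b.dG_ddag["ntp_association"] / b.RT)
    k3_ntp = k3 * params.pool[cand]
    q3 = eyring_rate(b.dG_ddag["ntp_dissociation"], ntp.dG_state, post.dG_state, b)
    kc = b.k_pre * np.exp(-b.dG_ddag["bond_formation"] / b.RT)
    qc = b.k_pre * np.exp(-b.dG_ddag["cleavage"] / b.RT)

    rates = StateRateSet(k1=k1, q1=q1, k2=k2, q2=q2, k3_ntp=k3_ntp, q3=q3,
                         kc=kc, qc=qc, position=i,
                         candidate_is_cognate=not cand_mismatch,
                         prior_mismatch_offset=prior_mismatch_offset)
    newest_mm = cand_mismatch or prior_mismatch_offset == 0
    cleavable_mm = prior_mismatch_offset in (0, 1)
    return apply_polymerase_effect(rates, newest_mm, cleavable_mm, pe.factor)


# ---------------------------------------------------------------------------
# Vectorized rate arrays over a whole template (shared by the per-position
# profile, the master equation and the Gillespie simulator).
# ---------------------------------------------------------------------------

@dataclass
class RateArrays:
    """Position-indexed rates of every cycle E_i, i in [i_start, i_end].

    Arrays are indexed j = i - i_start. Channels: 0 all-cognate, 1 mismatch
    at the 3' nucleotide i, 2 mismatch at the penultimate nucleotide i-1.
    q3 and kc depend additionally on the active-site step: ``q3_c``/``kc_c``
    cognate, ``q3_nc``/``kc_nc`` mismatched candidate, ``q3_mm``/``kc_mm``
    cognate candidate next to a 3' mismatch.
    """

    i_start: int
    i_end: int
    L: int
    k1: np.ndarray      # (3, n)
    q1: np.ndarray      # (3, n)
    k2: np.ndarray      # (n,)
    q2: np.ndarray      # (n,)
    k3N_c: np.ndarray   # (n,) cognate candidate at i+1
    k3N_nc: np.ndarray  # (n,) summed over the three non-cognate candidates
    q3_c: np.ndarray
    q3_nc: np.ndarray
    q3_mm: np.ndarray
    kc_c: float
    kc_nc: float
    kc_mm: float
    qc: np.ndarray      # (3,) per channel
    cog_next: np.ndarray  # (n,) RNA code (0..3) of the cognate base at i+1
    fingerprint: str = ""

    @property
    def n(self) -> int:
        return self.i_end - self.i_start + 1

    def j(self, i: int) -> int:
        if not (self.i_start <= i <= self.i_end):
            raise PositionOutOfRange(f"cycle E_{i} outside valid range "
                                     f"[{self.i_start}, {self.i_end}]")
        return i - self.i_start


def valid_cycle_range(L: int, geom) -> tuple[int, int]:
    """First and last elongation state whose four bubble windows fit."""
    h, m = geom.hybrid_bp, geom.melted_dna_bp
    return h + 1, L - (m - h) - 1


def _step_lookup_arrays(params: ModelParams):
    """16-entry dG arrays keyed by 4*code(first)+code(second) of the coding strand."""
    tables = params.tables
    dna16 = np.empty(16)
    hyb16 = np.empty(16)
    mmF16 = np.empty(16)  # pair at the first slot mismatched
    mmS16 = np.empty(16)  # pair at the second slot mismatched
    dna_comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for a, ca in enumerate("ACGT"):
        for bb, cb in enumerate("ACGT"):
            idx = 4 * a + bb
            dna16[idx] = lookup_step_dG(tables, DinucStep(
                DuplexClass.DNA_DNA, ca + cb, dna_comp[ca] + dna_comp[cb]))
            ra, rb = "ACGU"[a], "ACGU"[bb]
            ta, tb = dna_comp[ca], dna_comp[cb]
            hyb16[idx] = lookup_step_dG(tables, DinucStep(
                DuplexClass.RNA_DNA_WC, ra + rb, ta + tb))
            mmF16[idx] = lookup_step_dG(tables, DinucStep(
                DuplexClass.RNA_DNA_MISMATCH,
                template_mismatch_partner(ta) + rb, ta + tb, "first"))
            mmS16[idx] = lookup_step_dG(tables, DinucStep(
                DuplexClass.RNA_DNA_MISMATCH,
                ra + template_mismatch_partner(tb), ta + tb, "second"))
    return dna16, hyb16, mmF16, mmS16


def build_rate_arrays(coding_seq: str, params: ModelParams) -> RateArrays:
    """Vectorized equivalent of ``build_rate_set`` over all valid cycles."""
    coding_seq = coding_seq.upper()
    codes = encode_dna(coding_seq).astype(np.int64)
    L = len(codes)
    geom, b, pe = params.geometry, params.barriers, params.pe
    h, m = geom.hybrid_bp, geom.melted_dna_bp
    i_start, i_end = valid_cycle_range(L, geom)
    if i_end < i_start:
        raise ValueError(f"template of length {L} too short for the bubble")
    RT = b.RT

    dna16, hyb16, mmF16, mmS16 = _step_lookup_arrays(params)
    step_idx = 4 * codes[:-1] + codes[1:]           # step p covers (p, p+1), 0-based p-1
    dna_step = dna16[step_idx]
    hyb_step = hyb16[step_idx]
    dF = mmF16[step_idx] - hyb_step                 # penalty if first pair mismatched
    dS = mmS16[step_idx] - hyb_step                 # penalty if second pair mismatched

    # cumulative sums: S(a, b) = sum of steps a..b-1 (1-based pair window [a, b])
    Hd = np.concatenate([[0.0], np.cumsum(dna_step)])
    Hh = np.concatenate([[0.0], np.cumsum(hyb_step)])

    def Sd(a, bnd):
        return Hd[bnd - 1] - Hd[a - 1]

    def Sh(a, bnd):
        return Hh[bnd - 1] - Hh[a - 1]

    i = np.arange(i_start, i_end + 1)
    g_pre = -Sd(i - h + 1, i - h + m) + Sh(i - h + 1, i) + params.dG_pol
    g_post = -Sd(i - h + 2, i - h + m + 1) + Sh(i - h + 2, i) + params.dG_pol
    g_back = -Sd(i - h, i - h + m - 1) + Sh(i - h, i - 1) + params.dG_pol

    # channel free-energy shifts from a tracked mismatch (1-based step p = index p-1)
    dS_im1 = dS[i - 2]          # step (i-1, i)
    dF_im1 = dF[i - 2]          # step (i-1, i)
    dS_im2 = dS[i - 3]          # step (i-2, i-1)
    g_pre_ch = np.stack([g_pre, g_pre + dS_im1, g_pre + dF_im1 + dS_im2])
    g_back_ch = np.stack([g_back,
                          g_back - pe.back_stabilization_ddG,
                          g_back + dS_im2 - pe.back_stabilization_ddG])

    def eyr(barrier, g_from, g_to):
        return b.k_pre * np.exp(-(barrier + np.maximum(g_to - g_from, 0.0)) / RT)

    bb = b.dG_ddag
    k1 = eyr(bb["backstep"], g_pre_ch, g_back_ch)
    q1 = eyr(bb["backstep"], g_back_ch, g_pre_ch)
    k2 = eyr(bb["translocation"], g_pre, g_post)
    q2 = eyr(bb["translocation"], g_post, g_pre)

    hyb_i = hyb_step[i - 1]     # step (i, i+1)
    mmF_i = mmF16[step_idx][i - 1]
    mmS_i = mmS16[step_idx][i - 1]
    q3_of = lambda e: b.k_pre * np.exp(-(bb["ntp_dissociation"] + np.maximum(-e, 0.0)) / RT)
    q3_c, q3_nc, q3_mm = q3_of(hyb_i), q3_of(mmS_i), q3_of(mmF_i)

    k3 = b.k_pre * np.exp(-bb["ntp_association"] / RT)
    conc = np.array([params.pool[base] for base in "ACGU"])
    cog_next = codes[i]         # RNA code at position i+1
    k3N_c = k3 * conc[cog_next]
    k3N_nc = k3 * (conc.sum() - conc[cog_next])

    kc0 = b.k_pre * np.exp(-bb["bond_formation"] / RT)
    qc0 = b.k_pre * np.exp(-bb["cleavage"] / RT)
    qc = np.array([qc0, qc0 * pe.factor, qc0 * pe.factor])

    return RateArrays(
        i_start=i_start, i_end=i_end, L=L,
        k1=k1, q1=q1, k2=k2, q2=q2,
        k3N_c=k3N_c, k3N_nc=k3N_nc, q3_c=q3_c, q3_nc=q3_nc, q3_mm=q3_mm,
        kc_c=kc0, kc_nc=kc0 / pe.factor, kc_mm=kc0 / pe.factor,
        qc=qc, cog_next=cog_next.astype(np.int64),
        fingerprint=params.fingerprint())
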