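"""Polymerase revisits from downstream transcript cleavage and the resulting
accuracy amplification.

Cleavage from the backstepped sub-state of E_j removes the 3' dinucleotide
and returns the polymerase to E_{j-2}, so the last two transcript
nucleotides are scrutinized again: one extra round of first-step proofreading
for the then-3'-terminal nucleotide and one extra round of second-step
proofreading for the penultimate one. Expected visit counts N_j solve the
flow balance

    N_j = N_{j-1} * (1 - p_{j-1}) + N_{j+2} * p_{j+2}

where p_j is the per-visit cleavage probability of E_j (cognate rates: the
revisit traffic is dominated by correct incorporations), arrivals at the
first valid state are seeded to 1, and N vanishes beyond the template end.
The expected extra proofreading rounds at position p are then

    RV_last,p   = N_{p+2} * p_{p+2}      (re-entries into E_p)
    RV_penult,p = N_{p+3} * p_{p+3}      (re-entries into E_{p+1})

and the amplified accuracy is A_amp = I * F1^(1+RV_last) * F2^(1+RV_penult):
RV is an expectation, so fractional exponents amplify by the geometric mean
per expected round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .accuracy import AccuracyProfile, _sigma_kappa_vectors, RNA_BASES
from .kinetics import RateArrays, StateRateSet
from .params import ModelParams


def per_visit_cleavage_prob(rates: StateRateSet) -> float:
    """Probability that one visit to an elongation state ends in cleavage.

    p = (s/k) / (1 + s/k) from the compound cleavage/elongation ratio.
    """
    from .accuracy import sigma_kappa_ratio
    r = sigma_kappa_ratio(rates)
    return r / (1.0 + r)


def cleavage_prob_vector(ra: RateArrays) -> np.ndarray:
    """Per-visit cleavage probability of every valid cycle (cognate channel).

    The first two cycles cannot backstep-cleave without leaving the modeled
    region, so their probability is fixed at zero (mirrored by the simulator
    and the master equation).
    """
    r0, _, _ = _sigma_kappa_vectors(ra)
    p = r0 / (1.0 + r0)
    p[:2] = 0.0
    return p


def expected_visits(p: np.ndarray) -> np.ndarray:
    """Expected visit counts N_j from per-visit cleavage probabilities.

    Solves the linear flow-balance system; ``p[j] = 1`` anywhere means the
    polymerase never completes and is rejected.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("cleavage probabilities must lie in [0, 1)")
    n = len(p)
    # N_0 = 1 + N_2 p_2 ; N_j = N_{j-1}(1-p_{j-1}) + N_{j+2} p_{j+2}
    A = sp.lil_matrix((n, n))
    rhs = np.zeros(n)
    for j in range(n):
        A[j, j] = 1.0
        if j == 0:
            rhs[j] = 1.0
        else:
            A[j, j - 1] = -(1.0 - p[j - 1])
        if j + 2 < n:
            A[j, j + 2] = -p[j + 2]
    return spsolve(A.tocsr(), rhs)


@dataclass
class RevisitProfile:
    """Expected extra proofreading rounds and amplified accuracy per position."""

    per_position: pd.DataFrame   # RV_last, RV_penult indexed by position
    fingerprint: str


def revisit_profile(ra: RateArrays) -> RevisitProfile:
    """RV_last and RV_penult for every position of the accuracy profile."""
    from .accuracy import valid_profile_range
    p_vec = cleavage_prob_vector(ra)
    N = expected_visits(p_vec)
    cleavages = N * p_vec                       # expected cleavage events per cycle
    p_lo, p_hi = valid_profile_range(ra)
    pos = np.arange(p_lo, p_hi + 1)

    def at(i):
        j = i - ra.i_start
        out = np.zeros(len(pos))
        ok = (j >= 0) & (j < ra.n)
        out[ok] = cleavages[j[ok]]
        return out

    rv_last = at(pos + 2)
    rv_penult = at(pos + 3)
    df = pd.DataFrame({"RV_last": rv_last, "RV_penult": rv_penult},
                      index=pd.Index(pos, name="position"))
    return RevisitProfile(per_position=df, fingerprint=ra.fingerprint)


def amplified_accuracy(profile: AccuracyProfile, revisits: RevisitProfile,
                       params: ModelParams) -> AccuracyProfile:
    """Append revisit-amplified accuracy columns to a profile.

    A_amp = I * F1^(1+RV_last) * F2^(1+RV_penult); Err_amp = 1/(1+A_tot_amp)
    with the same concentration weighting as the base profile. Amplification
    never reduces accuracy because F1, F2 >= 1 wherever a mismatch
    destabilizes the bubble.
    """
    pos_df = profile.per_position
    if not pos_df.index.equals(revisits.per_position.index):
        raise ValueError("profile and revisit positions are not aligned")
    rv = revisits.per_position
    # log-space for numerical safety: strongly amplified positions can
    # overflow a direct product
    logA_amp = (np.log(pos_df["I"])
                + (1.0 + rv["RV_last"]) * np.log(pos_df["F1"])
                + (1.0 + rv["RV_penult"]) * np.log(pos_df["F2"]))
    conc = {x: params.pool[x] for x in RNA_BASES}
    weight = pos_df["cognate_base"].map(
        lambda cb: conc[cb] / sum(v for k, v in conc.items() if k != cb))
    out = pos_df.copy()
    out["RV_last"] = rv["RV_last"]
    out["RV_penult"] = rv["RV_penult"]
    out["A_amp"] = np.exp(logA_amp)
    out["A_tot_amp"] = np.exp(logA_amp + np.log(weight))
    out["Err_amp"] = np.maximum(
        np.exp(-np.logaddexp(0.0, logA_amp + np.log(weight))), 1e-300)
    return AccuracyProfile(sequence_id=profile.sequence_id,
                           per_competitor=profile.per_competitor,
                           per_position=out, fingerprint=profile.fingerprint,
                           excluded=profile.excluded)
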