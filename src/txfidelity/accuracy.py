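"""Closed-form selection-step accuracy: initial selection, two proofreading
steps, total accuracy and error frequency.

For a transcript position p three selection stages act in series:

* initial selection  I_p = (1 + (q3/kc)^nc) / (1 + (q3/kc)^c), evaluated in
  the cycle that incorporates p;
* first proofreading F1_p = (1 + (s/k)_p^nc) / (1 + (s/k)_p^c), where (s/k)_p
  is the ratio of the compound cleavage and elongation rate constants of
  elongation state E_p while the tracked base is 3'-terminal;
* second proofreading F2_p, the same ratio evaluated one state later
  (E_{p+1}) while the tracked base is penultimate.

The compound ratio is

    s/k = (k1/k2) * (1 + q2/(k3*[NTP]) * (1 + q3/kc)) / (1 + q1/qc)

and equals the splitting probability ratio cleave:elongate of the
four-sub-state chain (first-step analysis). The normalized accuracy per
competitor is A = I*F1*F2; the total accuracy against all three competing
NTPs weights each branch by its concentration, and Err = 1/(1 + A_tot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import RateArrays, StateRateSet, build_rate_arrays
from .params import ModelParams, NTPPool

RNA_BASES = "ACGU"


def pauling_discrimination(dG_d: float, T: float, R: float = 1.987e-3) -> float:
    """Pauling's maximum discrimination d = exp(-dG_d / (R*T)).

    ``dG_d`` is the free-energy difference (kcal/mol) between cognate and
    non-cognate substrate-template interaction; negative values favor the
    cognate substrate and give d > 1.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(-dG_d / (R * T)))


def initial_selection(rates_c: StateRateSet, rates_nc: StateRateSet) -> float:
    """I = (1 + (q3/kc)^nc) / (1 + (q3/kc)^c)."""
    return (1.0 + rates_nc.q3 / rates_nc.kc) / (1.0 + rates_c.q3 / rates_c.kc)


def sigma_kappa_ratio(rates: StateRateSet) -> float:
    """Compound cleavage/elongation ratio s/k of one elongation state.

    The rate set must already be built in the intended context: a 3'-terminal
    mismatch (first proofreading) carries modified k1, q1, q3, kc and qc; a
    penultimate mismatch (second proofreading) carries modified k1, q1 and qc
    while q3 and kc keep their cognate values because the active-site step is
    then a correct pair next to a correct pair.
    """
    inner = 1.0 + (rates.q2 / rates.k3_ntp) * (1.0 + rates.q3 / rates.kc)
    return (rates.k1 / rates.k2) * inner / (1.0 + rates.q1 / rates.qc)


def proofreading_F1(rates_c: StateRateSet, rates_nc: StateRateSet) -> float:
    """F1 = (1 + (s/k)^nc) / (1 + (s/k)^c) at elongation state E_p."""
    return (1.0 + sigma_kappa_ratio(rates_nc)) / (1.0 + sigma_kappa_ratio(rates_c))


def proofreading_F2(rates_c_next: StateRateSet, rates_nc_next: StateRateSet) -> float:
    """F2 from the compound ratios at E_{p+1} (tracked base penultimate)."""
    return (1.0 + sigma_kappa_ratio(rates_nc_next)) / (1.0 + sigma_kappa_ratio(rates_c_next))


def total_accuracy(A_by_competitor: dict[str, float], pool: NTPPool,
                   cognate: str, unweighted: bool = False) -> float:
    """Total accuracy against the three competing NTPs.

    A_tot = [S^c] / sum_k [S^nc_k] / A_k  — the cognate incorporation flux
    divided by the summed non-cognate fluxes, each competitor's flux being
    its concentration divided by its normalized accuracy A = I*F1*F2.
    With ``unweighted`` all concentrations are set equal.
    """
    competitors = [x for x in RNA_BASES if x != cognate]
    if set(A_by_competitor) != set(competitors):
        raise ValueError(f"need accuracies for exactly {competitors}")
    if unweighted:
        nc_flux = sum(1.0 / A_by_competitor[k] for k in competitors)
        return 1.0 / nc_flux
    nc_flux = sum(pool[k] / A_by_competitor[k] for k in competitors)
    return pool[cognate] / nc_flux


def error_frequency(A_tot: float) -> float:
    """Err = 1 / (1 + A_tot)."""
    if A_tot <= 0:
        raise ValueError("total accuracy must be positive")
    return 1.0 / (1.0 + A_tot)


@dataclass
class AccuracyProfile:
    """Per-position selection factors over the valid interior of a template.

    ``per_competitor`` has one row per (position, competitor) with I, F1, F2
    and A = I*F1*F2; ``per_position`` aggregates to A_tot and Err (both
    concentration-weighted and unweighted). Positions whose bubble windows
    do not fit are listed in ``excluded`` with the reason.
    """

    sequence_id: str
    per_competitor: pd.DataFrame
    per_position: pd.DataFrame
    fingerprint: str
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        return self.per_position.index.to_numpy()


def _sigma_kappa_vectors(ra: RateArrays) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(s/k) per cycle for the clean, 3'-mismatch and penultimate-mismatch channels."""
    inner_c = 1.0 + (ra.q2 / ra.k3N_c) * (1.0 + ra.q3_c / ra.kc_c)
    inner_m = 1.0 + (ra.q2 / ra.k3N_c) * (1.0 + ra.q3_mm / ra.kc_mm)
    r0 = (ra.k1[0] / ra.k2) * inner_c / (1.0 + ra.q1[0] / ra.qc[0])
    r1 = (ra.k1[1] / ra.k2) * inner_m / (1.0 + ra.q1[1] / ra.qc[1])
    r2 = (ra.k1[2] / ra.k2) * inner_c / (1.0 + ra.q1[2] / ra.qc[2])
    return r0, r1, r2


def valid_profile_range(ra: RateArrays) -> tuple[int, int]:
    """Positions with valid cycles at p-1 (I), p (F1) and p+1 (F2)."""
    return ra.i_start + 1, ra.i_end - 1


def profile_sequence(coding_seq: str, params: ModelParams,
                     sequence_id: str = "seq",
                     rate_arrays: RateArrays | None = None) -> AccuracyProfile:
    """Compute I, F1, F2, A, A_tot and Err at every valid template position.

    The three competitors at a position are the three non-cognate NTPs; with
    the grouped mismatch table they share selection factors and differ only
    through their concentrations in the weighted total.
    """
    coding_seq = coding_seq.upper()
    if len(coding_seq) == 0 or any(c not in "ACGT" for c in coding_seq):
        raise ValueError("sequence must be non-empty DNA over {A,C,G,T}")
    ra = rate_arrays if rate_arrays is not None else build_rate_arrays(coding_seq, params)
    p_lo, p_hi = valid_profile_range(ra)
    if p_hi < p_lo:
        raise ValueError("sequence shorter than the bubble span plus margins")
    p = np.arange(p_lo, p_hi + 1)
    jm1 = p - 1 - ra.i_start   # cycle E_{p-1}: incorporation of p
    j0 = p - ra.i_start        # cycle E_p: first proofreading
    j1 = p + 1 - ra.i_start    # cycle E_{p+1}: second proofreading

    I = (1.0 + ra.q3_nc[jm1] / ra.kc_nc) / (1.0 + ra.q3_c[jm1] / ra.kc_c)
    r0, r1, r2 = _sigma_kappa_vectors(ra)
    F1 = (1.0 + r1[j0]) / (1.0 + r0[j0])
    F2 = (1.0 + r2[j1]) / (1.0 + r0[j1])
    A = I * F1 * F2

    conc = np.array([params.pool[x] for x in RNA_BASES])
    cog = ra.cog_next[jm1]      # RNA code of position p
    nc_sum = conc.sum() - conc[cog]
    A_tot_w = conc[cog] * A / nc_sum
    A_tot_u = A / 3.0
    # stage-wise totals (cumulative: I; I*F1; I*F1*F2)
    weight = conc[cog] / nc_sum
    rows_pos = pd.DataFrame({
        "cognate_base": [RNA_BASES[c] for c in cog],
        "I": I, "F1": F1, "F2": F2, "A": A,
        "A_tot": A_tot_w, "Err": 1.0 / (1.0 + A_tot_w),
        "A_tot_unweighted": A_tot_u, "Err_unweighted": 1.0 / (1.0 + A_tot_u),
        "Err_I": 1.0 / (1.0 + weight * I),
        "Err_IF1": 1.0 / (1.0 + weight * I * F1),
        "Err_I_unweighted": 1.0 / (1.0 + I / 3.0),
        "Err_IF1_unweighted": 1.0 / (1.0 + I * F1 / 3.0),
    }, index=pd.Index(p, name="position"))

    comp_rows = []
    for k, pos in enumerate(p):
        cb = RNA_BASES[cog[k]]
        for x in RNA_BASES:
            if x == cb:
                continue
            comp_rows.append((pos, cb, x, I[k], F1[k], F2[k], A[k]))
    per_comp = pd.DataFrame(
        comp_rows, columns=["position", "cognate_base", "competitor",
                            "I", "F1", "F2", "A"])

    L = ra.L
    excluded = [(q, "bubble window out of range")
                for q in list(range(1, p_lo)) + list(range(p_hi + 1, L + 1))]
    return AccuracyProfile(sequence_id=sequence_id, per_competitor=per_comp,
                           per_position=rows_pos, fingerprint=ra.fingerprint,
                           excluded=excluded)


_STAGE_COLUMNS = {
    "I": "Err_I",
    "I*F1": "Err_IF1",
    "I*F1*F2": "Err",
    "I*F1*F2+revisits": "Err_amp",
}
_STAGE_COLUMNS_UNWEIGHTED = {
    "I": "Err_I_unweighted",
    "I*F1": "Err_IF1_unweighted",
    "I*F1*F2": "Err_unweighted",
}


def summarize_profile(profile: AccuracyProfile,
                      stages: tuple[str, ...] = ("I", "I*F1", "I*F1*F2"),
                      weighted: bool = True) -> pd.DataFrame:
    """Stage-wise error summaries.

    For each cumulative selection stage the table reports the log-scale
    average exp(mean(log(Err))), the per-nucleotide average mean(Err), and
    the factor by which each average decreased relative to the previous
    stage (the error reduction factor). With ``weighted=False`` the error
    columns with equal substrate concentrations are summarized instead.
    """
    if profile.per_position.empty:
        raise ValueError("empty profile")
    columns = _STAGE_COLUMNS if weighted else _STAGE_COLUMNS_UNWEIGHTED
    rows = []
    prev_log, prev_mean = None, None
    for stage in stages:
        col = columns.get(stage)
        if col is None or col not in profile.per_position:
            raise KeyError(f"unknown or unavailable stage {stage!r}")
        err = profile.per_position[col].to_numpy()
        log_avg = float(np.exp(np.mean(np.log(err))))
        mean_avg = float(np.mean(err))
        rows.append({
            "stage": stage,
            "err_log_average": log_avg,
            "err_per_nucleotide": mean_avg,
            "log_decrease_factor": (prev_log / log_avg) if prev_log else np.nan,
            "mean_decrease_factor": (prev_mean / mean_avg) if prev_mean else np.nan,
        })
        prev_log, prev_mean = log_avg, mean_avg
    return pd.DataFrame(rows).set_index("stage")
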