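"""Independent oracles used by the test suite.

These deliberately avoid the package's closed-form expressions: splitting
probabilities and first-passage times are obtained from dense linear algebra
on explicitly assembled absorbing Markov chains.
"""

import numpy as np

# state order inside one elongation cycle: PRE, POST, NTP, BACK
def splitting_cleave_prob(k1, q1, k2, q2, k3N, q3, kc, qc):
    """P(cleave before elongate | start in PRE) by first-step analysis.

    Absorbing chain over {PRE, POST, NTP, BACK} with absorption at CLEAVED
    (from BACK via qc) and ELONGATED (from NTP via kc).
    """
    A = np.array([
        [1.0, -k2 / (k1 + k2), 0.0, -k1 / (k1 + k2)],
        [-q2 / (q2 + k3N), 1.0, -k3N / (q2 + k3N), 0.0],
        [0.0, -q3 / (q3 + kc), 1.0, 0.0],
        [-q1 / (q1 + qc), 0.0, 0.0, 1.0],
    ])
    b = np.array([0.0, 0.0, 0.0, qc / (q1 + qc)])
    return float(np.linalg.solve(A, b)[0])


def sigma_kappa_oracle(rates):
    """Compound cleavage/elongation ratio from the splitting probability."""
    u = splitting_cleave_prob(rates.k1, rates.q1, rates.k2, rates.q2,
                              rates.k3_ntp, rates.q3, rates.kc, rates.qc)
    return u / (1.0 - u)


def bond_probability(q3, kc):
    """P(bond | NTP bound) from the 1-transient-state absorbing chain."""
    # absorbing solve: P = kc/(kc+q3) + 0; kept as an explicit linear solve
    A = np.array([[1.0]])
    b = np.array([kc / (kc + q3)])
    return float(np.linalg.solve(A, b)[0])


def dense_mfpt(Q_full, initial, absorbing):
    """Expected absorption time via the dense fundamental matrix."""
    Q = np.asarray(Q_full.todense()) if hasattr(Q_full, "todense") else np.asarray(Q_full)
    keep = [i for i in range(Q.shape[0]) if i != absorbing]
    Qtt = Q[np.ix_(keep, keep)]
    t = np.linalg.solve(-Qtt, np.ones(len(keep)))
    return float(t[keep.index(initial)])


def err_profile_oracle(seq, params):
    """Per-position error frequency by composing stage branch probabilities
    obtained from absorbing-chain solves (independent of the closed forms)."""
    from txfidelity.kinetics import build_rate_set, valid_cycle_range

    lo, hi = valid_cycle_range(len(seq), params.geometry)
    rna = seq.upper().replace("T", "U")
    out = {}
    for p in range(lo + 1, hi):
        cog = rna[p - 1]
        # stage probabilities per candidate
        rs_c_inc = build_rate_set(seq, p - 1, params)                      # incorporation of p
        rs_c_f1 = build_rate_set(seq, p, params)
        rs_nc_f1 = build_rate_set(seq, p, params, prior_mismatch_offset=0)
        rs_c_f2 = build_rate_set(seq, p + 1, params)
        rs_nc_f2 = build_rate_set(seq, p + 1, params, prior_mismatch_offset=1)
        P_I_c = bond_probability(rs_c_inc.q3, rs_c_inc.kc)
        sk = lambda r: splitting_cleave_prob(r.k1, r.q1, r.k2, r.q2, r.k3_ntp, r.q3, r.kc, r.qc)
        P_F1_c, P_F2_c = 1.0 - sk(rs_c_f1), 1.0 - sk(rs_c_f2)
        flux_c = params.pool[cog] * P_I_c * P_F1_c * P_F2_c
        flux_nc = 0.0
        for x in "ACGU":
            if x == cog:
                continue
            rs_x = build_rate_set(seq, p - 1, params, candidate=x)
            P_I_x = bond_probability(rs_x.q3, rs_x.kc)
            flux_nc += params.pool[x] * P_I_x * (1.0 - sk(rs_nc_f1)) * (1.0 - sk(rs_nc_f2))
        out[p] = flux_nc / (flux_c + flux_nc)
    return out
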