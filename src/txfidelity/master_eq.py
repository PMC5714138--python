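"""Total transcription time by mean first-passage analysis of the full
sub-state chain.

The chain couples every elongation cycle's sub-states (PRE, POST, POST.NTP
with a cognate or non-cognate substrate, BACK) including the non-cognate
branches: a non-cognate bond moves the complex into a 3'-mismatch channel,
a further cognate bond into a penultimate-mismatch channel, and any cleavage
deposits the complex in the post-translocated sub-state of E_{i-2} with the
mismatch (if any) removed — entry via cleavage thus differs from entry via
synthesis, which lands in PRE of the next state. The expected time from the
initial PRE state to completion of the transcript solves the linear system
Q t = -1 over the transient states (fundamental-matrix formulation).

``step1_only`` mode removes the mismatch-dependent rate modifications of the
cycle after a misincorporation (no penultimate-mismatch channel), isolating
the time cost of the second proofreading step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .kinetics import RateArrays, build_rate_arrays
from .params import ModelParams

# sub-state codes within one (cycle, channel) block
PRE, POST, NTP_C, NTP_NC, BACK = 0, 1, 2, 3, 4
_CHANNELS = {"clean": 0, "mm_last": 1, "mm_penult": 2}


@dataclass
class ChainModel:
    """Sparse continuous-time Markov chain of the whole template."""

    Q: sp.csr_matrix          # full generator, absorbing state last
    initial: int              # index of PRE at the first cycle
    absorbing: int            # completed transcript
    index: dict               # (cycle j, channel, substate) -> state index
    ra: RateArrays
    mode: str

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]


def build_chain(coding_seq: str, params: ModelParams,
                proofreading_mode: str = "two_step",
                rate_arrays: RateArrays | None = None) -> ChainModel:
    """Assemble the transition-rate generator for a template.

    Backstepping is disabled at the first two cycles (a cleavage there would
    leave the modeled region); the simulator applies the same convention.
    """
    if proofreading_mode not in ("two_step", "step1_only"):
        raise ValueError("mode must be 'two_step' or 'step1_only'")
    ra = rate_arrays if rate_arrays is not None else build_rate_arrays(coding_seq, params)
    n = ra.n
    if n < 3:
        raise ValueError("template too short for a meaningful chain")
    two_step = proofreading_mode == "two_step"

    index: dict = {}
    counter = 0
    channels = (0, 1, 2) if two_step else (0, 1)
    for j in range(n):
        for ch in channels:
            # a mismatch at the 3' nucleotide (ch 1) forbids non-cognate binding
            # (no consecutive mismatches); a penultimate mismatch does not
            subs = (PRE, POST, NTP_C, BACK) if ch == 1 else (PRE, POST, NTP_C, NTP_NC, BACK)
            for s in subs:
                index[(j, ch, s)] = counter
                counter += 1
    absorbing = counter
    n_states = counter + 1

    rows, cols, vals = [], [], []

    def add(a, b, rate):
        if rate > 0:
            rows.append(a)
            cols.append(b)
            vals.append(rate)

    for j in range(n):
        for ch in channels:
            pre = index[(j, ch, PRE)]
            post = index[(j, ch, POST)]
            ntpc = index[(j, ch, NTP_C)]
            back = index[(j, ch, BACK)]
            if j >= 2:
                add(pre, back, ra.k1[ch, j])
                add(back, pre, ra.q1[ch, j])
                # cleavage removes the 3' dinucleotide (and the mismatch, if
                # tracked) and re-enters POST of E_{j-2} in the clean channel
                add(back, index[(j - 2, 0, POST)], ra.qc[ch])
            else:
                add(back, pre, ra.q1[ch, j])
            add(pre, post, ra.k2[j])
            add(post, pre, ra.q2[j])
            # cognate substrate branch
            add(post, ntpc, ra.k3N_c[j])
            q3 = ra.q3_mm[j] if ch == 1 else ra.q3_c[j]
            kc = ra.kc_mm if ch == 1 else ra.kc_c
            add(ntpc, post, q3)
            if ch == 0:
                next_ch = 0
            elif ch == 1:
                next_ch = 2 if two_step else 0
            else:
                next_ch = 0
            if j + 1 < n:
                add(ntpc, index[(j + 1, next_ch, PRE)], kc)
            else:
                add(ntpc, absorbing, kc)
            if ch != 1:
                ntpnc = index[(j, ch, NTP_NC)]
                add(post, ntpnc, ra.k3N_nc[j])
                add(ntpnc, post, ra.q3_nc[j])
                if j + 1 < n:
                    add(ntpnc, index[(j + 1, 1, PRE)], ra.kc_nc)
                else:
                    add(ntpnc, absorbing, ra.kc_nc)

    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states)).tolil()
    out = np.asarray(Q.sum(axis=1)).ravel()
    Q.setdiag(Q.diagonal() - out)
    return ChainModel(Q=Q.tocsr(), initial=index[(0, 0, PRE)], absorbing=absorbing,
                      index=index, ra=ra, mode=proofreading_mode)


def mean_completion_time(chain: ChainModel) -> float:
    """Expected first-passage time from the initial state to absorption.

    Solves Q_tt * t = -1 over the transient states; a singular system means
    absorption is unreachable and is reported as an error.
    """
    t_idx = np.arange(chain.n_states - 1)  # absorbing state is last
    Qtt = chain.Q[t_idx][:, t_idx].tocsc()
    rhs = -np.ones(len(t_idx))
    t = spsolve(Qtt, rhs)
    if not np.all(np.isfinite(t)):
        raise np.linalg.LinAlgError("singular system: absorption unreachable")
    return float(t[chain.initial])


def total_transcription_time(coding_seq: str, params: ModelParams,
                             proofreading_mode: str = "two_step",
                             rate_arrays: RateArrays | None = None) -> float:
    """Transcription time of the full template.

    The chain covers the interior cycles whose bubble windows fit; the few
    edge positions are bridged at the interior's mean per-position time.
    """
    chain = build_chain(coding_seq, params, proofreading_mode, rate_arrays)
    t_region = mean_completion_time(chain)
    n = chain.ra.n
    L = chain.ra.L
    return t_region * L / n
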