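"""Numba core of the stochastic simulator (direct-method Gillespie).

One trajectory walks the sub-state machine of the whole template: sub-states
PRE, POST, POST.NTP (cognate or non-cognate substrate) and BACK per
elongation cycle. Misincorporated positions are flagged on the transcript so
cleavage and revisit bookkeeping are exact; a mismatch at the 3' nucleotide
forbids non-cognate binding (the model excludes consecutive mismatches),
while a penultimate mismatch does not. Cleavage removes the 3' dinucleotide
(clearing any mismatch it carries) and re-enters the post-translocated
sub-state two cycles back. Each trajectory draws its own RNG stream derived
from the master seed.
"""

import numpy as np
from numba import njit

S_PRE, S_POST, S_NTPC, S_NTPNC, S_BACK = 0, 1, 2, 3, 4


@njit(cache=True)
def _run_trajectories(k1, q1, k2, q2, k3N_c, k3N_nc, q3_c, q3_nc, q3_mm,
                      kc_c, kc_nc, kc_mm, qc0, qc_mm, conc, cog_next,
                      n_traj, master_seed, max_events):
    n = k2.shape[0]
    inc_total = np.zeros(n, dtype=np.int64)
    inc_err = np.zeros(n, dtype=np.int64)
    cleav = np.zeros(n, dtype=np.int64)
    reentry = np.zeros(n, dtype=np.int64)
    final_err = np.zeros(n, dtype=np.int64)
    times = np.zeros(n_traj)
    completed = np.zeros(n_traj, dtype=np.bool_)
    total_inc = np.zeros(n_traj, dtype=np.int64)
    total_cleaved = np.zeros(n_traj, dtype=np.int64)
    spectrum = np.zeros((16, 3), dtype=np.int64)

    err = np.zeros(n, dtype=np.int8)     # err[j]: base incorporated by cycle j mismatched
    base = np.zeros(n, dtype=np.int8)    # misincorporated identity where err[j] == 1
    for traj in range(n_traj):
        # one RNG stream per trajectory: splitmix-style hash of (seed, index)
        s = np.uint64(master_seed) + np.uint64(traj + 1) * np.uint64(0x9E3779B97F4A7C15)
        s = (s ^ (s >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        s = (s ^ (s >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        s = s ^ (s >> np.uint64(31))
        np.random.seed(s % np.uint64(2147483647))
        err[:] = 0
        j = 0            # current cycle index (elongation state E_{i_start + j})
        sub = S_PRE
        t = 0.0
        events = 0
        done = False
        while not done:
            events += 1
            if events > max_events:
                break
            mm_last = j >= 1 and err[j - 1] == 1
            mm_penult = j >= 2 and err[j - 2] == 1
            ch = 1 if mm_last else (2 if mm_penult else 0)

            if sub == S_PRE:
                r_back = k1[ch, j] if j >= 2 else 0.0
                tot = r_back + k2[j]
                u = np.random.random() * tot
                t += -np.log(np.random.random()) / tot
                sub = S_BACK if u < r_back else S_POST
            elif sub == S_POST:
                r_nc = 0.0 if mm_last else k3N_nc[j]
                tot = q2[j] + k3N_c[j] + r_nc
                u = np.random.random() * tot
                t += -np.log(np.random.random()) / tot
                if u < q2[j]:
                    sub = S_PRE
                elif u < q2[j] + k3N_c[j]:
                    sub = S_NTPC
                else:
                    sub = S_NTPNC
            elif sub == S_NTPC:
                q3 = q3_mm[j] if mm_last else q3_c[j]
                kc = kc_mm if mm_last else kc_c
                tot = q3 + kc
                u = np.random.random() * tot
                t += -np.log(np.random.random()) / tot
                if u < q3:
                    sub = S_POST
                else:
                    inc_total[j] += 1
                    total_inc[traj] += 1
                    err[j] = 0
                    j += 1
                    sub = S_PRE
                    if j >= n:
                        done = True
            elif sub == S_NTPNC:
                tot = q3_nc[j] + kc_nc
                u = np.random.random() * tot
                t += -np.log(np.random.random()) / tot
                if u < q3_nc[j]:
                    sub = S_POST
                else:
                    inc_total[j] += 1
                    inc_err[j] += 1
                    total_inc[traj] += 1
                    err[j] = 1
                    # competitor identity sampled by concentration
                    cog = cog_next[j]
                    wsum = 0.0
                    for b in range(4):
                        if b != cog:
                            wsum += conc[b]
                    v = np.random.random() * wsum
                    acc = 0.0
                    for b in range(4):
                        if b != cog:
                            acc += conc[b]
                            if v < acc:
                                base[j] = b
                                break
                    j += 1
                    sub = S_PRE
                    if j >= n:
                        done = True
            else:  # S_BACK
                qc = qc_mm if (mm_last or mm_penult) else qc0
                r_cleave = qc if j >= 2 else 0.0
                tot = q1[ch, j] + r_cleave
                u = np.random.random() * tot
                t += -np.log(np.random.random()) / tot
                if u < q1[ch, j]:
                    sub = S_PRE
                else:
                    # cleave the dinucleotide incorporated by cycles j-1 (3') and j-2
                    b_last = base[j - 1] if err[j - 1] else cog_next[j - 1]
                    b_pen = base[j - 2] if err[j - 2] else cog_next[j - 2]
                    slot = 0
                    if err[j - 2]:
                        slot = 1   # mismatch in the first (5') position of the fragment
                    elif err[j - 1]:
                        slot = 2   # mismatch in the second (3') position
                    spectrum[4 * b_pen + b_last, slot] += 1
                    cleav[j] += 1
                    total_cleaved[traj] += 2
                    err[j - 1] = 0
                    err[j - 2] = 0
                    j -= 2
                    reentry[j] += 1
                    sub = S_POST
        if done:
            completed[traj] = True
            times[traj] = t
            for jj in range(n):
                final_err[jj] += err[jj]
    return (inc_total, inc_err, cleav, reentry, final_err, times, completed,
            total_inc, total_cleaved, spectrum)
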