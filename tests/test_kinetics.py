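"""Eyring rates, detailed balance, locality and the polymerase effect."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txfidelity.io import generate_random_template
from txfidelity.kinetics import (apply_polymerase_effect, build_rate_arrays,
                                 build_rate_set, eyring_rate)
from txfidelity.params import default_params
from txfidelity.thermo import Substate, build_bubble_state, transcribe


@pytest.fixture(scope="module")
def p():
    return default_params()


class TestEyring:
    def test_barrierless_symmetric_gives_prefactor(self, p):
        b = p.barriers
        assert eyring_rate(0.0, -3.0, -3.0, b) == pytest.approx(b.k_pre)

    def test_forward_backward_ratio_is_boltzmann(self, p):
        b = p.barriers
        for dg1, dg2, bar in [(-1.0, 2.0, 3.0), (4.0, -0.5, 0.2), (0.0, 0.0, 5.0)]:
            fwd = eyring_rate(bar, dg1, dg2, b)
            bwd = eyring_rate(bar, dg2, dg1, b)
            assert fwd / bwd == pytest.approx(np.exp(-(dg2 - dg1) / b.RT))

    def test_rt_ln2_uphill_halves_rate(self, p):
        b = p.barriers
        down = eyring_rate(1.0, 0.0, -1.0, b)      # downhill: barrier only
        up = eyring_rate(1.0, 0.0, b.RT * np.log(2.0), b)
        assert down / up == pytest.approx(2.0)

    def test_negative_barrier_rejected(self, p):
        with pytest.raises(ValueError):
            eyring_rate(-0.1, 0.0, 0.0, p.barriers)

    @given(barrier=st.floats(0.0, 12.0), g1=st.floats(-8.0, 8.0),
           g2=st.floats(-8.0, 8.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_detailed_balance_holds_for_any_ground_states(self, barrier, g1, g2):
        from txfidelity.params import default_params
        b = default_params().barriers
        fwd, bwd = eyring_rate(barrier, g1, g2, b), eyring_rate(barrier, g2, g1, b)
        assert np.isclose(np.log(fwd) - np.log(bwd), -(g2 - g1) / b.RT,
                          rtol=0, atol=1e-9)
        assert max(fwd, bwd) == pytest.approx(
            b.k_pre * np.exp(-barrier / b.RT), rel=1e-12)


def test_detailed_balance_over_random_contexts(p):
    """k/q = exp(-ddG/RT) for both translocation pairs, every position and
    mismatch channel of a 1-kb random template (>1000 contexts)."""
    seq = str(generate_random_template(1010, 0.5, 17).seq)
    ra = build_rate_arrays(seq, p)
    geom, tables, RT = p.geometry, p.tables, p.barriers.RT
    rna = transcribe(seq)
    idx = np.linspace(0, ra.n - 1, 40).astype(int)
    for j in idx:
        i = ra.i_start + int(j)
        for off, ch in [(None, 0), (0, 1), (1, 2)]:
            offs = frozenset() if off is None else {off}
            g_pre = build_bubble_state(seq, i, Substate.PRE, tables, geom,
                                       mismatch_offsets=offs).dG_state
            g_post = build_bubble_state(seq, i, Substate.POST, tables, geom,
                                        mismatch_offsets=offs).dG_state
            g_back = build_bubble_state(seq, i, Substate.BACK, tables, geom,
                                        mismatch_offsets=offs).dG_state
            if off is not None:
                g_back -= p.pe.back_stabilization_ddG
            assert ra.k1[ch, j] / ra.q1[ch, j] == pytest.approx(
                np.exp(-(g_back - g_pre) / RT), rel=1e-12)
            assert ra.k2[j] / ra.q2[j] == pytest.approx(
                np.exp(-(g_post - g_pre) / RT), rel=1e-12)
    # vectorized full sweep for the clean channel
    assert np.allclose(np.log(ra.k1[0] / ra.q1[0]) + np.log(ra.k2 / ra.q2),
                       np.log(ra.k1[0] * ra.k2 / (ra.q1[0] * ra.q2)))


def test_rates_positive_finite_everywhere(p):
    seq = str(generate_random_template(500, 0.3, 23).seq)
    ra = build_rate_arrays(seq, p)
    for arr in (ra.k1, ra.q1, ra.k2, ra.q2, ra.k3N_c, ra.k3N_nc,
                ra.q3_c, ra.q3_nc, ra.q3_mm, ra.qc):
        assert np.all(arr > 0) and np.all(np.isfinite(arr))


def test_sequence_locality(p):
    """Rates of E_i are unchanged by mutations outside E_i's bubble windows."""
    seq = str(generate_random_template(80, 0.5, 31).seq)
    i = 40
    base = build_rate_set(seq, i, p)
    h, m = p.geometry.hybrid_bp, p.geometry.melted_dna_bp
    lo, hi = i - h, i + (m - h) + 2   # union of all sub-state windows (1-based)
    for pos in (lo - 3, hi + 2):
        mut = list(seq)
        mut[pos - 1] = "A" if mut[pos - 1] != "A" else "G"
        other = build_rate_set("".join(mut), i, p)
        for f in ("k1", "q1", "k2", "q2", "q3", "kc", "qc"):
            assert getattr(other, f) == getattr(base, f)


def test_translocation_rates_ignore_tracked_mismatch(p):
    """A mismatch at offset 0 or 1 lies inside both the PRE and POST windows,
    so its contribution cancels from k2/q2 exactly."""
    seq = str(generate_random_template(80, 0.5, 31).seq)
    clean = build_rate_set(seq, 40, p)
    for off in (0, 1):
        mm = build_rate_set(seq, 40, p, prior_mismatch_offset=off)
        assert mm.k2 == pytest.approx(clean.k2, rel=1e-12)
        assert mm.q2 == pytest.approx(clean.q2, rel=1e-12)


class TestPolymeraseEffect:
    def test_factor_one_is_identity(self, p):
        rs = build_rate_set(str(generate_random_template(60, 0.5, 2).seq), 30, p)
        assert apply_polymerase_effect(rs, True, True, 1.0) == rs

    def test_factor_50_ratios_at_3prime_mismatch(self, p):
        """kc^nc/kc^c = 1/50 and qc^nc/qc^c = 50 in the first proofreading
        context (mismatch at offset 0)."""
        seq = str(generate_random_template(60, 0.5, 2).seq)
        c = build_rate_set(seq, 30, p)
        nc = build_rate_set(seq, 30, p, prior_mismatch_offset=0)
        assert nc.kc / c.kc == pytest.approx(1 / 50)
        assert nc.qc / c.qc == pytest.approx(50)

    def test_second_step_context_leaves_kc_untouched(self, p):
        """With only a penultimate mismatch the active-site step is correct:
        kc is unaffected while cleavage discrimination remains."""
        seq = str(generate_random_template(60, 0.5, 2).seq)
        c = build_rate_set(seq, 30, p)
        nc = build_rate_set(seq, 30, p, prior_mismatch_offset=1)
        assert nc.kc == c.kc
        assert nc.qc / c.qc == pytest.approx(50)
        assert nc.q3 == pytest.approx(c.q3, rel=1e-12)

    def test_only_kc_qc_modified(self, p):
        rs = build_rate_set(str(generate_random_template(60, 0.5, 2).seq), 30, p)
        out = apply_polymerase_effect(rs, True, True, 7.0)
        for f in ("k1", "q1", "k2", "q2", "k3_ntp", "q3"):
            assert getattr(out, f) == getattr(rs, f)
        assert out.kc == rs.kc / 7.0 and out.qc == rs.qc * 7.0


def test_no_discrimination_without_energy_difference(neutral_params):
    """With mismatch energies equal to Watson-Crick values and the polymerase
    effect off, 'non-cognate' rate sets coincide with cognate ones exactly."""
    seq = str(generate_random_template(60, 0.5, 4).seq)
    rna = transcribe(seq)
    i = 30
    c = build_rate_set(seq, i, neutral_params)
    nc_base = [b for b in "ACGU" if b != rna[i]][0]
    nc = build_rate_set(seq, i, neutral_params, candidate=nc_base)
    assert nc.q3 == pytest.approx(c.q3, rel=1e-14)
    assert nc.kc == c.kc and nc.qc == c.qc
    mm = build_rate_set(seq, i, neutral_params, prior_mismatch_offset=0)
    for f in ("k1", "q1", "k2", "q2", "q3", "kc", "qc"):
        assert getattr(mm, f) == pytest.approx(getattr(c, f), rel=1e-14)


def test_rate_set_against_independent_recomputation(p):
    """All eight rates of one fixed context recomputed from the raw tables and
    the Eyring expression by standalone code."""
    seq = "ATGCGTACCGGATTACCAGTCGATCGGA"
    i = 14
    rs = build_rate_set(seq, i, p, prior_mismatch_offset=0)

    tables, geom, b = p.tables, p.geometry, p.barriers
    def G(sub, offs=frozenset(), cand=None):
        st = build_bubble_state(seq, i, sub, tables, geom, candidate=cand,
                                mismatch_offsets=offs, dG_pol=p.dG_pol)
        return st.dG_state
    RT = b.RT
    offs = {0}
    g_pre, g_post = G(Substate.PRE, offs), G(Substate.POST, offs)
    g_back = G(Substate.BACK, offs) - p.pe.back_stabilization_ddG
    g_ntp = G(Substate.POST_NTP, offs, cand=transcribe(seq)[i])
    kpre = b.k_pre
    exp = lambda bar, up: kpre * np.exp(-(bar + max(up, 0.0)) / RT)
    assert rs.k1 == pytest.approx(exp(b.dG_ddag["backstep"], g_back - g_pre), rel=1e-12)
    assert rs.q1 == pytest.approx(exp(b.dG_ddag["backstep"], g_pre - g_back), rel=1e-12)
    assert rs.k2 == pytest.approx(exp(b.dG_ddag["translocation"], g_post - g_pre), rel=1e-12)
    assert rs.q2 == pytest.approx(exp(b.dG_ddag["translocation"], g_pre - g_post), rel=1e-12)
    assert rs.q3 == pytest.approx(exp(b.dG_ddag["ntp_dissociation"], g_post - g_ntp), rel=1e-12)
    conc = p.pool[transcribe(seq)[i]]
    assert rs.k3_ntp == pytest.approx(conc * exp(b.dG_ddag["ntp_association"], 0.0), rel=1e-12)
    assert rs.kc == pytest.approx(exp(b.dG_ddag["bond_formation"], 0.0) / 50, rel=1e-12)
    assert rs.qc == pytest.approx(exp(b.dG_ddag["cleavage"], 0.0) * 50, rel=1e-12)


def test_vectorized_arrays_match_scalar_rate_sets(p, seq300):
    ra = build_rate_arrays(seq300, p)
    rna = transcribe(seq300)
    for i in (15, 100, 250):
        j = ra.j(i)
        clean = build_rate_set(seq300, i, p)
        assert np.allclose(
            [clean.k1, clean.q1, clean.k2, clean.q2, clean.k3_ntp, clean.q3, clean.kc, clean.qc],
            [ra.k1[0, j], ra.q1[0, j], ra.k2[j], ra.q2[j], ra.k3N_c[j], ra.q3_c[j],
             ra.kc_c, ra.qc[0]], rtol=1e-12)
        mm0 = build_rate_set(seq300, i, p, prior_mismatch_offset=0)
        assert np.allclose([mm0.k1, mm0.q1, mm0.q3, mm0.kc, mm0.qc],
                           [ra.k1[1, j], ra.q1[1, j], ra.q3_mm[j], ra.kc_mm, ra.qc[1]],
                           rtol=1e-12)
        mm1 = build_rate_set(seq300, i, p, prior_mismatch_offset=1)
        assert np.allclose([mm1.k1, mm1.q1, mm1.q3, mm1.kc, mm1.qc],
                           [ra.k1[2, j], ra.q1[2, j], ra.q3_c[j], ra.kc_c, ra.qc[2]],
                           rtol=1e-12)
        nc = build_rate_set(seq300, i, p,
                            candidate=[x for x in "ACGU" if x != rna[i]][0])
        assert np.allclose([nc.q3, nc.kc], [ra.q3_nc[j], ra.kc_nc], rtol=1e-12)
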