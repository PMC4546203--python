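import numpy as np
import pytest

from motifstdp.motifs import (
    STDPIntegrals, MotifODEConfig, stdp_integrals, frozen_operating_point,
    motif_rhs, integrate_motifs, unbalanced_solution,
    mean_weight_fixed_points, state_to_vector, vector_to_state, _COORDS,
)
from motifstdp.network import MotifState
from motifstdp.params import STDPRule, hebbian_rule, NoiseParams


def _state(**kw):
    base = dict(p=0.0, q_div=0.0, q_con=0.0, q_ch=0.0, q_rec=0.0, q_op=0.0,
                qX_rec=0.0, qX_div=0.0, qX_con=0.0, qX_chA=0.0, qX_chB=0.0,
                qX2_rec=0.0)
    base.update(kw)
    base["q_op"] = base["q_ch"] - base["q_rec"]
    return MotifState(**base)


class TestIntegrals:
    def test_area_identities(self):
        rule = STDPRule(f_plus=2e-3, f_minus=1.6e-3, tau_plus=20,
                        tau_minus=25)
        assert rule.S == pytest.approx(0.0, abs=1e-18)
        dep2 = hebbian_rule(f_plus=0.1, balance="depression_x2")
        assert dep2.S == pytest.approx(-0.1 * dep2.tau_plus)

    def test_hebbian_signs(self, frozen_ints):
        ints, _ = frozen_ints
        assert ints.S_F > 0 and ints.S_B < 0 and ints.S_C > 0
        ints.asserted_hebbian()

    def test_dual_quadrature_backward_integral(self, eif, noise, frozen_ints):
        """S_B by the Gauss-Legendre frequency quadrature vs a direct
        time-domain quadrature of L(s) against (C0 * K^-)(s)."""
        from motifstdp.covariance import synaptic_filter
        from motifstdp.fokker_planck import FrequencyGrid, compute_stats
        from motifstdp.covariance import freq_to_time

        ints, rule = frozen_ints
        grid = FrequencyGrid.uniform(1.0 / 2048, 4.0)
        st = compute_stats(ints.mu_eff, noise.sigma, eif, grid.omegas)
        K = st.A * synaptic_filter(grid.omegas)
        # integrate each side of the s=0 jump of L separately so the
        # trapezoid never straddles the discontinuity
        lags_n = np.arange(-350.0, 0.0 + 1e-9, 0.25)
        lags_p = np.arange(0.0, 350.0 + 1e-9, 0.25)
        g_n = freq_to_time(grid.omegas, st.C0 * np.conj(K), lags_n)
        g_p = freq_to_time(grid.omegas, st.C0 * np.conj(K), lags_p)
        L_n = -rule.f_minus * np.exp(lags_n / rule.tau_minus)
        L_p = rule.f_plus * np.exp(-lags_p / rule.tau_plus)
        SB_time = np.trapezoid(L_n * g_n, lags_n) \
            + np.trapezoid(L_p * g_p, lags_p)
        assert abs(SB_time - ints.S_B) < 1e-3 * abs(ints.S_B)

    def test_frozen_operating_point_self_consistency(self, eif, noise):
        r, mu_eff = frozen_operating_point(0.15, 5.0, noise, eif)
        from motifstdp.fokker_planck import stationary_rate

        assert stationary_rate(mu_eff, noise.sigma, eif) \
            == pytest.approx(r, rel=1e-8)
        assert mu_eff == pytest.approx(noise.mu + 5.0 * 2.5 * r)


# ---------------------------------------------------------------------------
# Independent second transcription of the closed motif system, written from
# the per-motif pattern (chance/forward/backward/common blocks) rather than
# equation by equation, as a double-entry check of the implementation.
# ---------------------------------------------------------------------------

def rhs_reference(y, cfg, ints):
    p, qd, qc, qch, qr, qx2, xr, xd, xc, xa, xb = y
    e = cfg.epsilon
    p0 = cfg.p0
    r2S = ints.r**2 * ints.S
    F, B, C = ints.S_F, ints.S_B, ints.S_C
    A2 = qd + p**2              # re-summed (q_div + p^2) block
    out = {}
    out["p"] = p0 * r2S + e * (p * F + (xr + p * p0) * B
                               + (p0 * A2 + p * (xc + xb)) / p0 * C)
    out["q_div"] = 2 * (r2S * xd + e * (qd * F + (p0 * qch + p * xd) * B
                        + (qch * (xc + p * p0) + xd * A2) / p0 * C))
    out["q_con"] = 2 * (r2S * xc + e * (qc * F + (p0 * qch + p * xc) * B
                        + (qc * (xb + p * p0) + xc * A2) / p0 * C))
    out["q_ch"] = r2S * (xa + xb) + e * (
        2 * qch * F + (p0 * (qc + qd) + p * (xa + xb)) * B
        + (A2 * (xa + xb) + qch * (xb + p * p0) + qc * (xc + p * p0)) / p0 * C)
    out["q_rec"] = 2 * e * (r2S * p0 * (xr + p * p0) + qr * F + qx2 * B)
    out["qX2_rec"] = 2 * e * (r2S * p0 * (xr + p * p0) + qx2 * F + qr * B)
    out["qX_rec"] = r2S * cfg.q0_rec + e * (
        xr * F + (1 - p0) * (xr + p * p0) * B
        + (cfg.q0_rec * A2 + xb * (xb + p * p0) + xc * (xc + p * p0)) / p0 * C)
    out["qX_div"] = r2S * cfg.q0_div + e * (
        xd * F + (p * cfg.q0_div + p0 * xb) * B
        + (cfg.q0_div * A2 + xb * (xc + p * p0)) / p0 * C)
    out["qX_con"] = r2S * cfg.q0_con + e * (
        xc * F + (p * cfg.q0_con + p0 * xa) * B
        + (cfg.q0_con * A2 + xc * (xb + p * p0)) / p0 * C)
    out["qX_chA"] = r2S * cfg.q0_ch + e * (
        xa * F + (p * cfg.q0_ch + p0 * xc) * B
        + (cfg.q0_ch * A2 + xc * (xc + p * p0)) / p0 * C)
    out["qX_chB"] = r2S * cfg.q0_ch + e * (
        xb * F + (p * cfg.q0_ch + p0 * xd) * B
        + (cfg.q0_ch * A2 + xb * (xb + p * p0)) / p0 * C)
    return np.array([out[k] for k in _COORDS])


@pytest.fixture(scope="module")
def ints_cfg(frozen_ints):
    ints, _ = frozen_ints
    cfg = MotifODEConfig(p0=0.15, q0_div=1.4e-4, q0_con=1.3e-4,
                         q0_ch=1.3e-6, q0_rec=2.0e-4, epsilon=1.0 / 150)
    return ints, cfg


class TestMotifRHS:
    def test_double_transcription_random_states(self, ints_cfg):
        ints, cfg = ints_cfg
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(scale=[0.5, 1e-2, 1e-2, 1e-2, 1e-3, 1e-3,
                                  1e-2, 1e-2, 1e-2, 1e-2, 1e-2])
            a = motif_rhs(y, cfg, ints)
            b = rhs_reference(y, cfg, ints)
            np.testing.assert_allclose(a, b, rtol=1e-13, atol=1e-300)

    def test_unstructured_invariant_set(self, ints_cfg):
        """With q0 == 0 and all motifs zero, every dq/dt vanishes and dp/dt
        reduces to the unstructured mean-field form."""
        ints, _ = ints_cfg
        cfg0 = MotifODEConfig(p0=0.15, q0_div=0, q0_con=0, q0_ch=0,
                              q0_rec=0, epsilon=1.0 / 150)
        p = 0.3
        y = np.zeros(11)
        y[0] = p
        d = motif_rhs(y, cfg0, ints)
        expected_dp = (cfg0.p0 * ints.r**2 * ints.S
                       + cfg0.epsilon * (p * (ints.S_F + cfg0.p0 * ints.S_B)
                                         + p**2 * ints.S_C))
        assert d[0] == pytest.approx(expected_dp, rel=1e-12)
        # the seven non-reciprocal motif coordinates are exactly stationary;
        # the reciprocal-conditioned ones carry an O(eps) source because
        # their unstructured baselines are themselves O(eps)
        for name, v in zip(_COORDS[1:], d[1:]):
            if name in ("q_rec", "qX2_rec", "qX_rec"):
                continue
            assert v == 0.0, name
        i_xr = _COORDS.index("qX_rec")
        src = cfg0.epsilon * (1 - cfg0.p0) * p * cfg0.p0 * ints.S_B
        assert d[i_xr] == pytest.approx(src, rel=1e-12)

    def test_unbalanced_leading_order(self, ints_cfg):
        """For |S| >> eps-terms the rhs collapses to dq = 2 r^2 S qX,
        dqX = r^2 S q0."""
        ints, cfg = ints_cfg
        big_S = STDPIntegrals(S=-2.0, S_F=ints.S_F, S_B=ints.S_B,
                              S_C=ints.S_C, r=ints.r, mu_eff=ints.mu_eff)
        import dataclasses

        rng = np.random.default_rng(1)
        y = rng.normal(scale=1e-2, size=11)
        cfg_small = dataclasses.replace(cfg, epsilon=1e-7)
        d = motif_rhs(y, cfg_small, big_S)
        r2S = big_S.r**2 * big_S.S
        i_qdiv, i_xd = _COORDS.index("q_div"), _COORDS.index("qX_div")
        assert d[i_qdiv] == pytest.approx(2 * r2S * y[i_xd], rel=1e-3)
        assert d[i_xd] == pytest.approx(r2S * cfg.q0_div, rel=1e-3)


class TestTrajectories:
    def test_invariant_set_preserved_along_flow(self, ints_cfg):
        ints, _ = ints_cfg
        cfg0 = MotifODEConfig(p0=0.15, q0_div=0, q0_con=0, q0_ch=0,
                              q0_rec=0, epsilon=1.0 / 150)
        t, states, _ = integrate_motifs(_state(p=0.4), cfg0, ints, T=3600.0)
        final = states[-1]
        for name in ("q_div", "q_con", "q_ch", "qX_div",
                     "qX_con", "qX_chA", "qX_chB"):
            assert abs(getattr(final, name)) < 1e-9
        # qX_rec drifts at O(eps) from its exact source term but stays small
        # (bounded by eps * p * p0 * |S_B| * T)
        bound = 2 * cfg0.epsilon * 1.0 * cfg0.p0 * abs(ints.S_B) * 3.6e6
        assert abs(final.qX_rec) < bound

    def test_chain_identity_along_trajectory(self, ints_cfg):
        ints, cfg = ints_cfg
        s0 = _state(p=0.375, q_div=8e-4, q_con=8e-4, q_ch=1e-5, q_rec=2e-4,
                    qX_rec=8e-4, qX_div=3e-4, qX_con=3e-4, qX_chA=1e-5,
                    qX_chB=1e-5, qX2_rec=1e-5)
        t, states, _ = integrate_motifs(s0, cfg, ints, T=1800.0)
        for s in states[:: len(states) // 5]:
            assert s.q_op == pytest.approx(s.q_ch - s.q_rec, abs=1e-15)

    def test_unbalanced_closed_form(self, ints_cfg):
        """Numerical trajectories under a strongly unbalanced rule match the
        quadratic-in-time closed forms to integrator tolerance."""
        ints, cfg = ints_cfg
        ub = STDPIntegrals(S=-2.0, S_F=0.0, S_B=0.0, S_C=0.0,
                           r=ints.r, mu_eff=ints.mu_eff)
        # closed forms drop the eps terms entirely: compare with S-only rhs
        s0 = _state(p=0.375, q_div=5e-4, q_con=4e-4, q_ch=1e-5,
                    qX_div=2e-4, qX_con=2e-4, qX_chA=5e-6, qX_chB=5e-6)
        cfg0 = MotifODEConfig(p0=cfg.p0, q0_div=cfg.q0_div,
                              q0_con=cfg.q0_con, q0_ch=cfg.q0_ch,
                              q0_rec=cfg.q0_rec, epsilon=0.0)
        T = 1200.0
        t, states, _ = integrate_motifs(s0, cfg0, ub, T=T)
        exact = unbalanced_solution(T * 1000.0, s0, cfg0, ub)
        got = states[-1]
        for name in ("p", "q_div", "q_con", "q_ch", "qX_div", "qX_con"):
            assert getattr(got, name) == pytest.approx(
                getattr(exact, name), rel=1e-6, abs=1e-14), name

    def test_unbalanced_solution_identity_and_expansion(self, ints_cfg):
        ints, cfg = ints_cfg
        s0 = _state(p=0.3, q_div=1e-4, qX_div=-2e-4)
        assert unbalanced_solution(0.0, s0, cfg, ints) == s0
        # depression-dominated (S < 0) but q0_div > 0: the quadratic S^2
        # term makes q_div grow at long times
        ub = STDPIntegrals(S=-2.0, S_F=0, S_B=0, S_C=0, r=ints.r,
                           mu_eff=ints.mu_eff)
        late = unbalanced_solution(5e6, s0, cfg, ub)
        assert late.q_div > s0.q_div
        assert late.p < s0.p


class TestNullclineScan:
    def test_signs_partition_the_plane(self, ints_cfg):
        """In the (q_div, q_con) plane the scanned rhs signs change
        monotonically along each axis (the nullclines project to nearly
        straight lines there), and the scan matches pointwise rhs calls."""
        from motifstdp.motifs import nullcline_scan

        ints, cfg = ints_cfg
        s0 = _state(p=0.375, qX_div=1e-4, qX_con=1e-4)
        df = nullcline_scan(s0, cfg, ints, ("q_div", "q_con"),
                            (-2e-3, 6e-3), (-2e-3, 6e-3), n=9)
        assert len(df) == 81
        assert set(df["sign_q_div"].unique()) <= {-1, 0, 1}
        # spot check one grid point against motif_rhs
        row = df.iloc[40]
        y = state_to_vector(s0)
        y[_COORDS.index("q_div")] = row["q_div"]
        y[_COORDS.index("q_con")] = row["q_con"]
        d = motif_rhs(y, cfg, ints)
        assert row["d_q_div"] == pytest.approx(d[_COORDS.index("q_div")])


class TestFixedPoints:
    def test_perfect_balance_roots(self, ints_cfg):
        ints, cfg = ints_cfg
        bal = STDPIntegrals(S=0.0, S_F=ints.S_F, S_B=ints.S_B, S_C=ints.S_C,
                            r=ints.r, mu_eff=ints.mu_eff)
        roots = mean_weight_fixed_points(cfg, bal)
        vals = sorted(p for p, _ in roots)
        b = ints.S_F + cfg.p0 * ints.S_B
        assert vals[1] == pytest.approx(0.0, abs=1e-12)
        assert vals[0] == pytest.approx(-b / ints.S_C, rel=1e-10)

    def test_depression_dominated_signs_and_stability(self, frozen_ints):
        ints, _ = frozen_ints
        cfg = MotifODEConfig(p0=0.15, q0_div=0, q0_con=0, q0_ch=0, q0_rec=0,
                             epsilon=1.0 / 150)
        roots = mean_weight_fixed_points(cfg, ints)   # S < 0 preset
        assert len(roots) == 2
        (p_lo, lab_lo), (p_hi, lab_hi) = roots
        assert p_lo < 0 < p_hi
        assert lab_hi == "unstable"

    def test_separatrix_increases_with_connection_probability(
            self, eif, noise):
        seps = []
        for p0 in (0.05, 0.1, 0.15, 0.2, 0.25):
            rule_hat = hebbian_rule(balance="depression", delta=0.1,
                                    epsilon=1.0 / (1000 * p0))
            ints = stdp_integrals(rule_hat, p0=p0, noise=noise, eif=eif)
            cfg = MotifODEConfig(p0=p0, q0_div=0, q0_con=0, q0_ch=0,
                                 q0_rec=0, epsilon=1.0 / (1000 * p0))
            roots = [p for p, lab in mean_weight_fixed_points(cfg, ints)
                     if p > 0]
            seps.append(roots[0])
        assert np.all(np.diff(seps) > 0)
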