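import numpy as np
import pytest

from motifstdp.covariance import (
    full_covariance, truncated_covariance, freq_to_time, synaptic_filter,
    FrequencyQuadrature, rule_weighted_integrals, spectral_radius,
)
from motifstdp.fokker_planck import (
    FrequencyGrid, NeuronStatsTable, compute_stats, self_consistent_rates,
)
from motifstdp.network import WeightedNetwork, make_erdos_renyi, uniform_weights
from motifstdp.params import NoiseParams, SimConfig, hebbian_rule


@pytest.fixture(scope="module")
def grid():
    return FrequencyGrid.uniform()


def _net_stats(net, eif, sigma, omegas):
    r, mu_eff = self_consistent_rates(net, 1.0, sigma, eif, 5.0)
    table = NeuronStatsTable(mu_eff, sigma, eif, omegas, n_nodes=5)
    return (table.A_matrix(mu_eff), table.C0_matrix(mu_eff)), r


class TestFullCovariance:
    def test_uncoupled_equals_baseline(self, eif, grid):
        N = 3
        net = WeightedNetwork(np.zeros((N, N), np.int8), np.zeros((N, N)),
                              wmax=1.0, epsilon=1.0)
        stats, _ = _net_stats(net, eif, 9.0, grid.omegas)
        cs = full_covariance(net, stats, grid.omegas)
        for k in range(grid.M):
            assert np.allclose(np.diag(cs.C_omega[k]), stats[1][:, k])
            off = cs.C_omega[k] - np.diag(np.diag(cs.C_omega[k]))
            assert np.abs(off).max() == 0.0

    def test_feedforward_pair_closed_form(self, eif, grid):
        """W*K is nilpotent for a feedforward pair, so the Neumann series
        terminates: the cross term is exactly W01 * A0 * J * C0_11 and the
        truncation is exact off the diagonal."""
        W0 = np.array([[0, 1], [0, 0]], np.int8)
        net = WeightedNetwork(W0, W0 * 1.5, wmax=5.0, epsilon=1.0)
        stats, _ = _net_stats(net, eif, 9.0, grid.omegas)
        A, C0 = stats
        cs = full_covariance(net, stats, grid.omegas)
        ct = truncated_covariance(net, stats, grid.omegas)
        closed = 1.5 * A[0] * synaptic_filter(grid.omegas) * C0[1]
        assert np.abs(cs.C_omega[:, 0, 1] - closed).max() \
            < 1e-12 * np.abs(closed).max()
        for (i, j) in [(0, 1), (1, 0)]:
            assert np.allclose(cs.C_omega[:, i, j], ct.C_omega[:, i, j])

    def test_hermitian_positive_semidefinite(self, eif, grid):
        net = uniform_weights(make_erdos_renyi(8, 0.4, seed=1), wmax=5.0)
        # strengthen weights but stay stable
        net.W = net.W * 3.0
        net.wmax *= 3.0
        stats, _ = _net_stats(net, eif, 9.0, grid.omegas)
        cs = full_covariance(net, stats, grid.omegas)
        for k in range(0, grid.M, 97):
            Ck = cs.C_omega[k]
            assert np.abs(Ck - Ck.conj().T).max() < 1e-12
            w = np.linalg.eigvalsh(Ck)
            assert w.min() > -1e-10 * np.trace(Ck).real

    def test_neumann_series_consistency(self, eif, grid):
        """Partial sums sum_{a,b<=n} G^a C0 G^H^b converge to the full solve,
        and the n=1 off-diagonal partial sum is the truncation."""
        net = uniform_weights(make_erdos_renyi(6, 0.5, seed=2), wmax=5.0)
        stats, _ = _net_stats(net, eif, 9.0, grid.omegas)
        A, C0 = stats
        k = grid.n_half  # omega = 0
        G = (A[:, k] * synaptic_filter(0.0))[:, None] * net.W
        D = np.diag(C0[:, k]).astype(complex)
        stats0 = (A[:, [k]], C0[:, [k]])
        full = full_covariance(net, stats0, np.array([0.0])).C_omega[0]
        errs = []
        for n in (1, 3, 8, 20):
            S = sum(np.linalg.matrix_power(G, a) for a in range(n + 1))
            approx = S @ D @ S.conj().T
            errs.append(np.abs(approx - full).max())
        assert errs[-1] < 1e-8 * np.abs(full).max()
        assert errs[0] > errs[1] > errs[2]
        trunc = truncated_covariance(net, stats0, np.array([0.0])).C_omega[0]
        n1 = G @ D + D @ G.conj().T + G @ D @ G.conj().T
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(trunc[off], n1[off])

    def test_spectral_radius_check(self, eif):
        net = uniform_weights(make_erdos_renyi(10, 0.5, seed=3), wmax=5.0)
        net.W = net.W * 500.0   # grossly unstable coupling
        net.wmax *= 500.0
        st = compute_stats(1.0, 9.0, eif, np.array([0.0]))
        stats = (np.tile(st.A, (10, 1)), np.tile(st.C0, (10, 1)))
        with pytest.raises(RuntimeError, match="linearization invalid"):
            full_covariance(net, stats, np.array([0.0]))


class TestTransforms:
    def test_lorentzian_pair(self):
        """The exponential-synapse filter transforms back to an exponential:
        analytic check of the inverse transform at < 0.1%."""
        tau = 8.0
        wide = FrequencyGrid.uniform(1.0 / 512, 16.0)
        spec = 2 * tau / (1 + (2 * np.pi * wide.omegas * tau) ** 2)
        lags = np.arange(0.0, 100.0, 0.5)
        back = freq_to_time(wide.omegas, spec, lags)
        exact = np.exp(-lags / tau)
        assert np.abs(back - exact).max() < 1e-3

    def test_time_symmetry_pairs(self, eif, grid):
        net = uniform_weights(make_erdos_renyi(5, 0.6, seed=4), wmax=5.0)
        stats, _ = _net_stats(net, eif, 9.0, grid.omegas)
        cs = full_covariance(net, stats, grid.omegas)
        lags = grid.lag_grid()
        Cab = cs.time_domain(lags, pairs=[(0, 1)])[:, 0]
        Cba = cs.time_domain(lags, pairs=[(1, 0)])[:, 0]
        assert np.abs(Cab - Cba[::-1]).max() < 1e-10 * np.abs(Cab).max()

    def test_aliasing_detection(self):
        omegas = np.arange(-10, 11) * (1.0 / 512)   # far too narrow a band
        spec = synaptic_filter(omegas, 8.0)          # has not decayed at edge
        with pytest.raises(ValueError, match="aliasing"):
            freq_to_time(omegas, spec, np.array([0.0, 1.0]))

    def test_parseval_rule_weighted_integral(self, eif, grid):
        """int L(s) C_ij(s) ds computed by the Gauss-Legendre frequency
        quadrature equals the time-domain quadrature to < 0.1%."""
        W0 = np.array([[0, 1], [1, 0]], np.int8)
        net = WeightedNetwork(W0, np.array([[0, 1.2], [0.7, 0]]),
                              wmax=5.0, epsilon=1.0)
        rule = hebbian_rule(f_plus=0.01, epsilon=1.0)
        quad = FrequencyQuadrature.build()
        stats_q, _ = _net_stats(net, eif, 9.0, quad.nodes)
        Xp, Xm = rule_weighted_integrals(net, stats_q, rule, "full",
                                         quad=quad)
        X_freq = (Xp + Xm)[0, 1]
        fine = FrequencyGrid.uniform(1.0 / 2048, 4.0)
        stats_f, _ = _net_stats(net, eif, 9.0, fine.omegas)
        cs = full_covariance(net, stats_f, fine.omegas)
        # integrate each side of the s=0 jump of L separately
        ln = np.arange(-350.0, 0.0 + 1e-9, 0.25)
        lp = np.arange(0.0, 350.0 + 1e-9, 0.25)
        Cn = cs.time_domain(ln, pairs=[(0, 1)])[:, 0]
        Cp = cs.time_domain(lp, pairs=[(0, 1)])[:, 0]
        X_time = np.trapezoid(-rule.f_minus * np.exp(ln / rule.tau_minus)
                              * Cn, ln) \
            + np.trapezoid(rule.f_plus * np.exp(-lp / rule.tau_plus) * Cp, lp)
        assert abs(X_freq - X_time) < 1e-3 * abs(X_time)


class TestAgainstSimulation:
    def test_network_covariance_matches_simulation(self, eif, noise):
        """Weakly coupled ER network: theory C_ij(s) integrated over a lag
        window agrees with the empirical estimate within Monte-Carlo error."""
        net = uniform_weights(make_erdos_renyi(30, 0.2, seed=5), wmax=5.0)
        net.W = net.W * 2.0    # weak coupling (~0.33 uA/cm^2 per synapse)
        net.wmax *= 2.0
        grid = FrequencyGrid.uniform()
        stats, _ = _net_stats(net, eif, 9.0, grid.omegas)
        cs = full_covariance(net, stats, grid.omegas)
        from motifstdp.simulate import estimate_cross_covariance

        T = 400_000.0
        spikes, _, _ = simulate_net(net, eif, noise, T, seed=6)
        pairs = [(0, j) for j in range(1, 10)]
        lags_e, cov = estimate_cross_covariance(spikes, 1.0, 50.0, pairs=pairs)
        lags_t = grid.lag_grid()
        Ct = cs.time_domain(lags_t, pairs=pairs)
        r = spikes.rates()
        n_ok = 0
        for col, (i, j) in enumerate(pairs):
            emp = np.trapezoid(cov[(i, j)], lags_e)
            th = np.trapezoid(
                np.interp(lags_e, lags_t, Ct[:, col]), lags_e)
            # MC error of the +-50 ms integral: nearly independent 1 ms lag
            # bins, each with variance ~ r_i r_j / (T bin)
            se = np.sqrt(100.0 * r[i] * r[j] / T)
            if abs(emp - th) < 3 * se:
                n_ok += 1
        assert n_ok >= 8   # allow one 3-sigma outlier among nine pairs


def simulate_net(net, eif, noise, T, seed):
    from motifstdp.simulate import simulate

    return simulate(net, eif, noise, None, SimConfig(dt=0.05, T=T, seed=seed))
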