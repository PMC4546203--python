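"""Ground-truth stochastic simulation of the plastic EIF network.

Euler-Maruyama integration of

    C dV_i = [gL (VL - V_i) + gL Delta e^{(V_i-VT)/Delta} + mu + x_i(t)] dt
             + gL sigma D [sqrt(1-c) dW_i + sqrt(c) dW_common]

where x_i(t) = sum_j W_ij s_j(t) is the recurrent synaptic current built from
exponential synapses (decay tauS, unit jump per presynaptic spike, amplitude
W_ij).  Spikes are thresholded at Vth, reset to Vre and held for tau_ref.
The shared noise component can be white or an Ornstein-Uhlenbeck process
normalized to carry the same zero-frequency spectral density as white noise.

Online plasticity implements the additive all-to-all pair rule through two
exponential traces per neuron (decay tau_plus / tau_minus), which makes every
pre/post pair interact exactly in O(1) work per spike; simultaneous pre/post
spikes (lag zero) are credited to potentiation.  Weights are hard-clipped to
[0, wmax] and non-edges never change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import EIFParams, NoiseParams, SimConfig, STDPRule, TAU_S_DEFAULT
from .network import WeightedNetwork

__all__ = [
    "SpikeData",
    "simulate",
    "simulate_single",
    "estimate_cross_covariance",
    "spike_count_correlations",
    "CountCorrelations",
]


@dataclass
class SpikeData:
    """Per-neuron ordered spike-time lists (ms)."""

    trains: list          # list of float64 arrays
    T: float
    N: int

    @classmethod
    def from_flat(cls, spk_t: np.ndarray, spk_i: np.ndarray, N: int, T: float
                  ) -> "SpikeData":
        order = np.argsort(spk_t, kind="stable")
        spk_t, spk_i = spk_t[order], spk_i[order]
        trains = [spk_t[spk_i == i] for i in range(N)]
        return cls(trains=trains, T=T, N=N)

    def rates(self) -> np.ndarray:
        """Empirical rates, spikes/ms."""
        return np.array([t.size for t in self.trains]) / self.T

    def binned(self, bin_ms: float) -> np.ndarray:
        """(N, n_bins) spike-count matrix."""
        n_bins = int(self.T // bin_ms)
        counts = np.zeros((self.N, n_bins))
        for i, t in enumerate(self.trains):
            idx = (t / bin_ms).astype(np.int64)
            idx = idx[idx < n_bins]
            np.add.at(counts[i], idx, 1.0)
        return counts

    def to_csv(self, path) -> None:
        rows = np.concatenate(
            [np.column_stack([np.full(t.size, i), t]) for i, t in
             enumerate(self.trains) if t.size] or [np.empty((0, 2))]
        )
        np.savetxt(path, rows, fmt=("%d", "%.6f"), delimiter=",",
                   header="neuron_id,time_ms")


@njit(cache=True)
def _run_network(
    W, mask, dt, n_steps,
    Cm, gL, VL, Delta, VT, Vth, Vre, ref_steps,
    mu, noise_amp, c, common_is_ou, ou_tau,
    tauS,
    plastic, f_plus, f_minus, tau_plus, tau_minus, wmax,
    rec_every, W_rec,
    rate_cap, seed,
    spk_t, spk_i,
):
    np.random.seed(seed)
    N = W.shape[0]
    V = Vre + (VT - Vre) * np.random.random(N)
    ref = np.zeros(N, np.int64)
    syn = np.zeros(N)
    tr_p = np.zeros(N)
    tr_m = np.zeros(N)
    dec_syn = math.exp(-dt / tauS)
    dec_p = math.exp(-dt / tau_plus)
    dec_m = math.exp(-dt / tau_minus)
    sq_dt = math.sqrt(dt)
    amp_priv = noise_amp * math.sqrt(1.0 - c)
    amp_comm = noise_amp * math.sqrt(c)
    z_ou = np.random.standard_normal()   # unit stationary variance
    n_spk = 0
    cap = spk_t.shape[0]
    spikers = np.empty(N, np.int64)
    block_steps = max(int(1000.0 / dt), 1)
    block_count = 0
    n_rec = 0
    status = 0

    for step in range(n_steps):
        t = step * dt
        # shared noise draw happens every step so that toggling c does not
        # shift the private streams
        xi_c = np.random.standard_normal()
        common_current = 0.0
        if common_is_ou:
            z_ou += -z_ou / ou_tau * dt + math.sqrt(2.0 / ou_tau) * sq_dt * xi_c
            common_current = amp_comm * z_ou
        n_now = 0
        for i in range(N):
            xi = np.random.standard_normal()
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = Vre
                continue
            ex = (V[i] - VT) / Delta
            if ex > 30.0:
                ex = 30.0
            drift = (gL * (VL - V[i]) + gL * Delta * math.exp(ex)
                     + mu + syn[i] + common_current) / Cm
            dnoise = amp_priv * sq_dt * xi
            if not common_is_ou:
                dnoise += amp_comm * sq_dt * xi_c
            V[i] += drift * dt + dnoise / Cm
            if V[i] >= Vth:
                spikers[n_now] = i
                n_now += 1
                V[i] = Vre
                ref[i] = ref_steps
                if n_spk < cap:
                    spk_t[n_spk] = t
                    spk_i[n_spk] = i
                n_spk += 1
        if n_spk > cap:
            status = 2
            break
        block_count += n_now
        if (step + 1) % block_steps == 0:
            if block_count / (N * block_steps * dt) > rate_cap:
                status = 1
                break
            block_count = 0
        # propagate spikes through the synapses
        for s in range(n_now):
            j = spikers[s]
            for i in range(N):
                syn[i] += W[i, j]
        if plastic and n_now > 0:
            # depression: presynaptic spike j pairs with earlier post spikes i
            for s in range(n_now):
                j = spikers[s]
                for i in range(N):
                    if mask[i, j] and W[i, j] > 0.0:
                        W[i, j] -= f_minus * tr_m[i]
                        if W[i, j] < 0.0:
                            W[i, j] = 0.0
            for s in range(n_now):
                tr_p[spikers[s]] += 1.0
            # potentiation: postsynaptic spike i pairs with pre spikes j,
            # including simultaneous ones (lag zero)
            for s in range(n_now):
                i = spikers[s]
                for j in range(N):
                    if mask[i, j] and W[i, j] < wmax:
                        W[i, j] += f_plus * tr_p[j]
                        if W[i, j] > wmax:
                            W[i, j] = wmax
            for s in range(n_now):
                tr_m[spikers[s]] += 1.0
        # decay traces and synaptic drive
        for i in range(N):
            syn[i] *= dec_syn
        if plastic:
            for i in range(N):
                tr_p[i] *= dec_p
                tr_m[i] *= dec_m
        if rec_every > 0 and (step + 1) % rec_every == 0:
            if n_rec < W_rec.shape[0]:
                for i in range(N):
                    for j in range(N):
                        W_rec[n_rec, i, j] = W[i, j]
                n_rec += 1
    return n_spk, n_rec, status


def simulate(
    net: WeightedNetwork,
    eif: EIFParams,
    noise: NoiseParams,
    stdp: STDPRule | None,
    cfg: SimConfig,
    tauS: float = TAU_S_DEFAULT,
):
    """Simulate the network; returns (SpikeData, weight_times, weight_snaps).

    ``stdp`` may be None (or ``cfg.plasticity_on`` False) for a static run.
    Raises RuntimeError on rate instability (network mean rate above
    ``cfg.rate_cap`` in any 1 s block).
    """
    N = net.N
    n_steps = int(round(cfg.T / cfg.dt))
    ref_steps = int(round(eif.tau_ref / cfg.dt))
    noise_amp = eif.gL * noise.sigma * noise.D(eif)
    plastic = bool(cfg.plasticity_on and stdp is not None)
    rule = stdp if stdp is not None else STDPRule(0.0, 0.0)

    rec_every = 0
    n_rec_max = 0
    if plastic and cfg.record_weights_every > 0:
        rec_every = max(int(round(cfg.record_weights_every / cfg.dt)), 1)
        n_rec_max = n_steps // rec_every
    W_rec = np.zeros((n_rec_max, N, N))

    cap = max(int(N * cfg.T * cfg.rate_cap * 1.05), 4096)
    spk_t = np.zeros(cap)
    spk_i = np.zeros(cap, np.int32)
    W = net.W.copy()

    n_spk, n_rec, status = _run_network(
        W, net.W0.astype(np.bool_), cfg.dt, n_steps,
        eif.C, eif.gL, eif.VL, eif.Delta, eif.VT, eif.Vth, eif.Vre, ref_steps,
        noise.mu, noise_amp, noise.c, noise.common_kind == "OU", noise.ou_tau,
        tauS,
        plastic, rule.f_plus, rule.f_minus, rule.tau_plus, rule.tau_minus,
        rule.wmax,
        rec_every, W_rec,
        cfg.rate_cap, int(cfg.seed) & 0x7FFFFFFF,
        spk_t, spk_i,
    )
    if status != 0:
        raise RuntimeError(
            "rate instability: network mean rate exceeded the configured cap"
        )
    spikes = SpikeData.from_flat(spk_t[:n_spk], spk_i[:n_spk], N, cfg.T)
    w_times = (np.arange(1, n_rec + 1) * rec_every * cfg.dt)
    net.W = W  # final weights (unchanged when plasticity is off)
    return spikes, w_times, W_rec[:n_rec]


def simulate_single(
    eif: EIFParams, mu: float, sigma: float, T: float, dt: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Spike times of one uncoupled EIF neuron (Monte-Carlo oracle)."""
    from .network import WeightedNetwork as _WN

    net = _WN(W0=np.zeros((2, 2), np.int8), W=np.zeros((2, 2)),
              wmax=1.0, epsilon=1.0)
    noise = NoiseParams(mu=mu, sigma=sigma)
    spikes, _, _ = simulate(net, eif, noise, None,
                            SimConfig(dt=dt, T=T, seed=seed))
    return spikes.trains[0]


# ---------------------------------------------------------------------------
# Empirical spike statistics
# ---------------------------------------------------------------------------

def estimate_cross_covariance(
    spikes: SpikeData, bin_ms: float, max_lag: float,
    pairs: list | None = None,
):
    """Binned spike-train cross-covariance on a lag grid.

    Returns (lags, cov) with ``cov[(i, j)]`` the function C_ij(s) in
    spikes^2/ms^2: counts are binned at ``bin_ms``, demeaned (which subtracts
    the rate product), correlated at every lag that is a multiple of the bin,
    and normalized by the overlapping duration.  C_ij(s) = C_ji(-s) holds
    exactly by construction.
    """
    if max_lag % bin_ms > 1e-9 and abs(max_lag % bin_ms - bin_ms) > 1e-9:
        raise ValueError("bin must divide max_lag")
    counts = spikes.binned(bin_ms)
    N, n_bins = counts.shape
    if pairs is None:
        pairs = [(i, j) for i in range(N) for j in range(N) if i <= j]
    k_max = int(round(max_lag / bin_ms))
    lags = np.arange(-k_max, k_max + 1) * bin_ms
    x = counts - counts.mean(axis=1, keepdims=True)
    if not np.any(counts):
        import warnings

        warnings.warn("empty spike trains: covariance is zero", RuntimeWarning)
    n_fft = 1
    while n_fft < 2 * n_bins:
        n_fft *= 2
    X = np.fft.rfft(x, n_fft, axis=1)
    out = {}
    norm = (n_bins - np.abs(np.arange(-k_max, k_max + 1))) * bin_ms**2
    for (i, j) in pairs:
        full = np.fft.irfft(X[i] * np.conj(X[j]), n_fft)
        # full[k] = sum_t x_i(t+k) x_j(t); lag s > 0 means neuron i (the
        # postsynaptic index of W_ij) spikes after neuron j
        cc = np.concatenate([full[-k_max:], full[: k_max + 1]])
        out[(i, j)] = cc / norm
        out[(j, i)] = out[(i, j)][::-1]
    return lags, out


@dataclass
class CountCorrelations:
    all_pairs: float
    connected_pairs: float
    window: float
    n_silent: int


def spike_count_correlations(
    spikes: SpikeData, window: float, W0: np.ndarray,
) -> CountCorrelations:
    """Mean Pearson correlation of spike counts in disjoint windows,
    over all pairs and over directly connected pairs (either direction).
    Silent neurons are excluded from both averages."""
    counts = spikes.binned(window)
    if counts.shape[1] < 50:
        raise ValueError("need at least 50 windows; reduce window or extend T")
    active = counts.sum(axis=1) > 0
    n_silent = int((~active).sum())
    idx = np.where(active)[0]
    Ccoef = np.corrcoef(counts[idx])
    iu = np.triu_indices(idx.size, k=1)
    all_mean = float(np.nanmean(Ccoef[iu]))
    conn = (W0 + W0.T)[np.ix_(idx, idx)] > 0
    conn_vals = Ccoef[iu][conn[iu]]
    conn_mean = float(np.nanmean(conn_vals)) if conn_vals.size else float("nan")
    return CountCorrelations(all_mean, conn_mean, window, n_silent)
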