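"""Self-consistent evolution of every synaptic weight.

Fast-slow averaging gives the drift of each existing synapse

    dW_ij/dt = W0_ij * int L(s) (r_i r_j + C_ij(s)) ds

with the covariances taken from linear-response theory at the current weight
matrix.  The bound factors of the rule gate the potentiation and depression
contributions separately: the potentiation branch is zeroed where
W_ij >= wmax and the depression branch where W_ij <= 0; the Euler update is
then clipped to [0, wmax].

Three covariance flavors are available: the full dense solve, the
length-one-path truncation (both per neuron), and a homogeneous truncation
that replaces every neuron's kernels by the network average - the same
approximation the reduced motif theory rests on, and cheap enough for
N ~ 10^3 networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import EIFParams, NoiseParams, STDPRule, TAU_S_DEFAULT
from .network import WeightedNetwork, motif_strengths
from .fokker_planck import (
    NeuronStatsTable, compute_stats, self_consistent_rates,
)
from .covariance import (
    FrequencyQuadrature, rule_weighted_integrals, synaptic_filter,
    spectral_radius,
)

__all__ = ["weight_drift", "evolve", "TheoryTrajectory"]


def _branch_rates(rule: STDPRule, r: np.ndarray):
    """Rate-term contributions of each branch: r_i r_j * (area of branch)."""
    rr = np.outer(r, r)
    return rr * rule.f_plus * rule.tau_plus, -rr * rule.f_minus * rule.tau_minus


def weight_drift(
    net: WeightedNetwork,
    rule: STDPRule,
    noise: NoiseParams,
    eif: EIFParams,
    tauS: float = TAU_S_DEFAULT,
    flavor: str = "full",
    quad: FrequencyQuadrature | None = None,
    n_mu_nodes: int = 5,
    return_rates: bool = False,
):
    """dW/dt (weight per ms) for every synapse at the current network state."""
    if quad is None:
        quad = FrequencyQuadrature.build()
    r, mu_eff = self_consistent_rates(net, noise.mu, noise.sigma, eif, tauS)
    if flavor in ("full", "truncated"):
        table = NeuronStatsTable(mu_eff, noise.sigma, eif, quad.nodes,
                                 n_nodes=n_mu_nodes)
        Xp, Xm = rule_weighted_integrals(net, (table, mu_eff), rule,
                                         flavor=flavor, tauS=tauS, quad=quad)
    elif flavor == "truncated_homog":
        stats = compute_stats(float(np.mean(mu_eff)), noise.sigma, eif,
                              quad.nodes)
        Xp, Xm = _homog_truncated_integrals(net, stats, rule, tauS, quad)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    Rp, Rm = _branch_rates(rule, r)
    pot = (Rp + Xp) * (net.W < rule.wmax)
    dep = (Rm + Xm) * (net.W > 0.0)
    dW = net.W0 * (pot + dep)
    if return_rates:
        return dW, r, mu_eff
    return dW


def _homog_truncated_integrals(net, stats, rule, tauS, quad):
    """Rule-weighted truncated covariance integrals with network-averaged
    kernels: X = SF*W + SB*W^T + SC*(W W^T) per branch, where the S factors
    are scalar quadratures of L±(omega)* against K C0, C0 K*, |K|^2 C0."""
    omegas = quad.nodes
    K = stats.A * synaptic_filter(omegas, tauS)
    C0 = stats.C0
    two_pi_i = 2j * np.pi * omegas
    Lp = rule.f_plus * rule.tau_plus / (1.0 + two_pi_i * rule.tau_plus)
    Lm = -rule.f_minus * rule.tau_minus / (1.0 - two_pi_i * rule.tau_minus)
    out = []
    WWt = net.W @ net.W.T
    for L in (Lp, Lm):
        sf = quad.integrate(np.conj(L) * K * C0)
        sb = quad.integrate(np.conj(L) * C0 * np.conj(K))
        sc = quad.integrate(np.conj(L) * np.abs(K) ** 2 * C0)
        out.append(sf * net.W + sb * net.W.T + sc * WWt)
    return out[0], out[1]


@dataclass
class TheoryTrajectory:
    """Weight / rate / motif snapshots along the slow plasticity flow.

    ``times`` are in seconds of biological time; ``weights[k]`` is the full
    weight matrix at ``times[k]``.
    """

    times: np.ndarray
    weights: np.ndarray          # (n_t, N, N)
    rates: np.ndarray            # (n_t, N)
    motifs: list                 # list of MotifState
    error: str | None = None

    def mean_weight(self) -> np.ndarray:
        return self.weights.mean(axis=(1, 2))

    def motif_table(self):
        import pandas as pd

        rows = [m.as_dict() for m in self.motifs]
        df = pd.DataFrame(rows)
        df.insert(0, "time_s", self.times)
        return df

    def to_hdf5(self, path, group: str = "trajectory") -> None:
        import h5py

        with h5py.File(path, "a") as f:
            g = f.require_group(group)
            for name, data in (("times", self.times),
                               ("weights", self.weights),
                               ("rates", self.rates)):
                if name in g:
                    del g[name]
                g.create_dataset(name, data=data)
            if self.error:
                g.attrs["error"] = self.error


def evolve(
    net: WeightedNetwork,
    rule: STDPRule,
    noise: NoiseParams,
    eif: EIFParams,
    T_total: float,
    step: float = 100.0,
    tauS: float = TAU_S_DEFAULT,
    flavor: str = "full",
    quad: FrequencyQuadrature | None = None,
    n_mu_nodes: int = 5,
) -> TheoryTrajectory:
    """Euler-step the self-consistent theory.

    ``T_total`` and ``step`` are in seconds of biological time (drift rates
    are per ms internally).  The network is re-linearized at every step; on a
    mid-trajectory rate instability the trajectory is truncated and returned
    with an error flag.
    """
    if quad is None:
        quad = FrequencyQuadrature.build()
    net = net.copy()
    n_steps = int(round(T_total / step))
    times = [0.0]
    weights = [net.W.copy()]
    motifs = [motif_strengths(net)]
    rates_list = []
    error = None
    for k in range(n_steps):
        try:
            dW, r, _ = weight_drift(net, rule, noise, eif, tauS, flavor,
                                    quad, n_mu_nodes, return_rates=True)
        except RuntimeError as exc:
            error = str(exc)
            rates_list.append(np.full(net.N, np.nan))
            break
        rates_list.append(r)
        net.W = np.clip(net.W + dW * step * 1000.0, 0.0, rule.wmax) * net.W0
        times.append((k + 1) * step)
        weights.append(net.W.copy())
        motifs.append(motif_strengths(net))
    rates_list.append(rates_list[-1] if rates_list else np.full(net.N, np.nan))
    n_t = len(times)
    return TheoryTrajectory(
        times=np.asarray(times),
        weights=np.asarray(weights),
        rates=np.asarray(rates_list[:n_t]),
        motifs=motifs,
        error=error,
    )
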