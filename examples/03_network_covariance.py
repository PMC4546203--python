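"""Linear-response spiking covariances versus direct simulation.

Builds a small Erdos-Renyi EIF network, solves the full covariance matrix
C(omega) = (I-G)^-1 C0 (I-G)^-H, and compares the predicted windowed
spike-count correlations with a plasticity-off simulation.
"""

import numpy as np

from motifstdp import (
    EIFParams, FrequencyGrid, NeuronStatsTable, NoiseParams, SimConfig,
    full_covariance, make_erdos_renyi, self_consistent_rates, simulate,
    spike_count_correlations, uniform_weights,
)

eif, noise = EIFParams(), NoiseParams()
net = uniform_weights(make_erdos_renyi(100, 0.15, seed=2), wmax=5.0)

r, mu_eff = self_consistent_rates(net, noise.mu, noise.sigma, eif, 5.0)
grid = FrequencyGrid.uniform(1 / 2048, 0.5)
table = NeuronStatsTable(mu_eff, noise.sigma, eif, grid.omegas)
cs = full_covariance(net, (table, mu_eff), grid.omegas)

Tw = 100.0
om = grid.omegas
win = np.where(np.abs(om) < 1e-12, Tw**2,
               (np.sin(np.pi * om * Tw) / (np.pi * np.where(om == 0, 1, om)))**2)
cov = np.tensordot(win, cs.C_omega.real, axes=(0, 0)) * (om[1] - om[0])
sd = np.sqrt(np.diag(cov))
rho = cov / np.outer(sd, sd)
iu = np.triu_indices(net.N, k=1)
conn = ((net.W0 + net.W0.T) > 0)[iu]

spikes, _, _ = simulate(net, eif, noise, None,
                        SimConfig(dt=0.05, T=100_000.0, seed=4))
cc = spike_count_correlations(spikes, Tw, net.W0)

print(f"N = {net.N} Erdos-Renyi network, mean rate "
      f"{spikes.rates().mean() * 1000:.1f} Hz, {Tw:.0f} ms windows")
print(f"mean count correlation, all pairs:      theory {rho[iu].mean():.4f}"
      f"   simulation {cc.all_pairs:.4f}")
print(f"mean count correlation, connected pairs: theory "
      f"{rho[iu][conn].mean():.4f}   simulation {cc.connected_pairs:.4f}")
print("Recurrent coupling alone generates these weak correlations; "
      "directly connected pairs are a few-fold more correlated.")
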