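"""Networks with correlated truncated power-law degree distributions.

In- and out-degrees follow a two-piece power law (exponents 0.2 and -1,
break at N/10, cutoff at N) coupled through a Gaussian copula with
correlation rho.  Positive rho makes high-in-degree neurons also
high-out-degree, which raises the chain-motif frequency q0_ch - the lever
that distinguishes chain-rich from chain-poor networks in the motif
dynamics.
"""

import warnings

import numpy as np

from motifstdp import DegreeDistConfig, make_degree_correlated, \
    motif_frequencies

N = 1000
warnings.simplefilter("ignore", RuntimeWarning)
for rho in (-0.1, 0.1, 0.5):
    cfg = DegreeDistConfig(L1=N / 10, L2=float(N), rho=rho,
                           mean_degree=0.15 * N)
    stats = [motif_frequencies(make_degree_correlated(N, cfg, s))
             for s in range(5)]
    qd = np.mean([f.q0_div for f in stats])
    qc = np.mean([f.q0_con for f in stats])
    qch = np.mean([f.q0_ch for f in stats])
    print(f"rho = {rho:+.1f}: q0_div = {qd:.4f}  q0_con = {qc:.4f}  "
          f"q0_ch = {qch:+.5f}")
print("q0_div and q0_con are ~100x larger than in an Erdos-Renyi graph and "
      "insensitive to rho; q0_ch tracks the in/out-degree correlation.")
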