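"""Deterministic canned objects used by examples, tests and the CLI.

Every fixture is regenerated from (name, seed) and is bit-identical across
calls; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np

from .params import (
    EIFParams, NoiseParams, DegreeDistConfig, hebbian_rule, WMAX_DEFAULT,
)
from .network import (
    WeightedNetwork, make_erdos_renyi, make_degree_correlated, uniform_weights,
)

__all__ = ["make_fixture", "FIXTURES"]


def _pair(recip: bool, c: float, common_kind: str, w12: float, w21: float):
    W0 = np.array([[0, 1], [1 if recip else 0, 0]], np.int8)
    W = np.array([[0.0, w12], [w21 if recip else 0.0, 0.0]])
    net = WeightedNetwork(W0=W0, W=W, wmax=WMAX_DEFAULT, epsilon=1.0)
    noise = NoiseParams(mu=1.0, sigma=9.0, c=c, common_kind=common_kind,
                        ou_tau=5.0)
    return net, noise


def _triple_enumerable(seed):
    # edges 2 -> 1 and 2 -> 3 (entry (i, j) = synapse j -> i), 0-indexed
    W0 = np.zeros((3, 3), np.int8)
    W0[0, 1] = 1
    W0[2, 1] = 1
    return W0


def _powerlaw(N, rho, seed):
    cfg = DegreeDistConfig(gamma1=0.2, gamma2=-1.0, L1=N / 10, L2=float(N),
                           rho=rho, mean_degree=0.15 * N)
    return make_degree_correlated(N, cfg, seed)


FIXTURES = {
    # circuits
    "pair_reciprocal": lambda seed: _pair(True, 0.0, "white", 2.6, 2.2),
    "pair_common_input": lambda seed: _pair(True, 0.05, "OU", 2.6, 2.2),
    "pair_feedforward": lambda seed: _pair(False, 0.0, "white", 2.5, 0.0),
    "triple_enumerable": _triple_enumerable,
    # Erdos-Renyi adjacencies
    "er_tiny": lambda seed: make_erdos_renyi(50, 0.15, seed),
    "er_small": lambda seed: make_erdos_renyi(100, 0.15, seed),
    "er_default": lambda seed: make_erdos_renyi(1000, 0.15, seed),
    # correlated truncated power-law degree networks
    "powerlaw_rho-0.1": lambda seed: _powerlaw(1000, -0.1, seed),
    "powerlaw_rho0.1": lambda seed: _powerlaw(1000, 0.1, seed),
    "powerlaw_rho0.5": lambda seed: _powerlaw(1000, 0.5, seed),
    # STDP presets (unscaled amplitudes; scale by epsilon for a network)
    "stdp_balanced_dep": lambda seed: hebbian_rule(balance="depression",
                                                   delta=0.1,
                                                   epsilon=1.0 / 150),
    "stdp_balanced_pot": lambda seed: hebbian_rule(balance="potentiation",
                                                   delta=0.1,
                                                   epsilon=1.0 / 150),
    "stdp_depression_x2": lambda seed: hebbian_rule(balance="depression_x2"),
    "stdp_potentiation_x2": lambda seed: hebbian_rule(balance="potentiation_x2"),
}


def make_fixture(name: str, seed: int = 0):
    """Build a named fixture; unknown names raise with the available list."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return factory(seed)
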