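"""Network generation and two-synapse motif statistics.

Matrix orientation: row = postsynaptic, column = presynaptic, so entry (i, j)
is the synapse j -> i.  Adjacency matrices are binary with a structurally zero
diagonal (no autapses); weight matrices are nonnegative and supported on the
adjacency.

Motif conventions
-----------------
Motif *frequencies* (q0) are moments of the binary adjacency matrix with the
chance level p0^2 subtracted.  Motif *strengths* (q) are the analogous moments
of the weight matrix, explicitly rescaled by the mean in-degree through
epsilon = 1/(N p0): the mean weight coordinate p satisfies eps*p = mean(W), so
p ranges over [0, p0*wmax] when actual weights range over [0, eps*wmax].
Mixed motifs (qX) condition the strength of one synapse on the second leg of
the motif existing in the adjacency matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .params import DegreeDistConfig

__all__ = [
    "WeightedNetwork",
    "MotifFrequencies",
    "MotifState",
    "make_erdos_renyi",
    "make_degree_correlated",
    "motif_frequencies",
    "motif_strengths",
    "uniform_weights",
]


def _validate_adjacency(W0: np.ndarray) -> np.ndarray:
    W0 = np.asarray(W0)
    if W0.ndim != 2 or W0.shape[0] != W0.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if np.any(np.diag(W0) != 0):
        raise ValueError("adjacency has nonzero diagonal (autapses forbidden)")
    vals = np.unique(W0)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    return W0.astype(np.int8, copy=False)


@dataclass
class WeightedNetwork:
    """Binary adjacency ``W0`` plus nonnegative weight matrix ``W``.

    ``wmax`` bounds the weights elementwise and ``epsilon = 1/(N p0)`` records
    the weight rescaling used for the motif coordinates.
    """

    W0: np.ndarray
    W: np.ndarray
    wmax: float
    epsilon: float

    def __post_init__(self) -> None:
        self.W0 = _validate_adjacency(self.W0)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != self.W0.shape:
            raise ValueError("W and W0 shapes differ")
        if np.any(self.W[self.W0 == 0] != 0):
            raise ValueError("weights must vanish off the adjacency support")
        if np.any(self.W < 0) or np.any(self.W > self.wmax * (1 + 1e-12)):
            raise ValueError("weights must lie in [0, wmax]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def N(self) -> int:
        return self.W0.shape[0]

    @property
    def p0(self) -> float:
        return float(self.W0.sum()) / self.N**2

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.W0.copy(), self.W.copy(), self.wmax, self.epsilon)

    # ---- I/O ----------------------------------------------------------
    def to_hdf5(self, path, group: str = "network", **attrs) -> None:
        import h5py

        with h5py.File(path, "a") as f:
            g = f.require_group(group)
            for name, arr in (("W0", self.W0), ("W", self.W)):
                if name in g:
                    del g[name]
                g.create_dataset(name, data=arr)
            g.attrs["N"] = self.N
            g.attrs["wmax"] = self.wmax
            g.attrs["epsilon"] = self.epsilon
            g.attrs["p0"] = self.p0
            for k, v in attrs.items():
                g.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path, group: str = "network") -> "WeightedNetwork":
        import h5py

        with h5py.File(path, "r") as f:
            g = f[group]
            return cls(
                W0=g["W0"][()],
                W=g["W"][()],
                wmax=float(g.attrs["wmax"]),
                epsilon=float(g.attrs["epsilon"]),
            )

    def to_csv(self, path_w0, path_w) -> None:
        """Dense CSV dump; first header line records N."""
        for path, arr, fmt in ((path_w0, self.W0, "%d"), (path_w, self.W, "%.17g")):
            np.savetxt(path, arr, fmt=fmt, delimiter=",", header=f"N={self.N}")

    @classmethod
    def from_csv(cls, path_w0, path_w, wmax: float, epsilon: float
                 ) -> "WeightedNetwork":
        W0 = np.loadtxt(path_w0, delimiter=",", comments="#")
        W = np.loadtxt(path_w, delimiter=",", comments="#")
        return cls(W0=W0.astype(np.int8), W=W, wmax=wmax, epsilon=epsilon)


def uniform_weights(
    W0: np.ndarray,
    p0: float | None = None,
    wmax: float = 5.0,
    fill_fraction: float = 0.5,
) -> WeightedNetwork:
    """Weighted network with every existing synapse at ``fill_fraction`` of
    the epsilon-rescaled maximum weight eps*wmax - the standard uniform
    initial condition (mean-weight coordinate p = fill_fraction * p0 * wmax).
    """
    W0 = _validate_adjacency(W0)
    N = W0.shape[0]
    if p0 is None:
        p0 = float(W0.sum()) / N**2
    eps = 1.0 / (N * p0)
    W = W0.astype(float) * (fill_fraction * eps * wmax)
    return WeightedNetwork(W0=W0, W=W, wmax=eps * wmax, epsilon=eps)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_erdos_renyi(N: int, p0: float, seed: int) -> np.ndarray:
    """Erdos-Renyi digraph: each off-diagonal entry independently 1 w.p. p0."""
    if N < 2:
        raise ValueError("N must be at least 2")
    if not 0 < p0 <= 1:
        raise ValueError("p0 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    W0 = (rng.random((N, N)) < p0).astype(np.int8)
    np.fill_diagonal(W0, 0)
    return W0


def _powerlaw_constants(cfg: DegreeDistConfig) -> tuple[float, float]:
    """Normalization constants (C1, C2) of the continuous two-piece density,
    continuous at L1 and integrating to one on [0, L2]."""
    g1, g2, L1, L2 = cfg.gamma1, cfg.gamma2, cfg.L1, cfg.L2
    if g1 <= -1:
        raise ValueError("gamma1 must exceed -1 for an integrable head")
    head = L1 ** (g1 + 1) / (g1 + 1)              # integral of d^g1 on [0, L1]
    if abs(g2 + 1) < 1e-12:
        tail = np.log(L2 / L1)                    # integral of d^-1 on [L1, L2]
    else:
        tail = (L2 ** (g2 + 1) - L1 ** (g2 + 1)) / (g2 + 1)
    # continuity: C1 L1^g1 = C2 L1^g2  =>  C2 = C1 * L1^(g1-g2)
    ratio = L1 ** (g1 - g2)
    C1 = 1.0 / (head + ratio * tail)
    return C1, C1 * ratio


def _powerlaw_ppf(u: np.ndarray, cfg: DegreeDistConfig) -> np.ndarray:
    """Inverse CDF of the continuous truncated power law."""
    g1, g2, L1, L2 = cfg.gamma1, cfg.gamma2, cfg.L1, cfg.L2
    C1, C2 = _powerlaw_constants(cfg)
    F_L1 = C1 * L1 ** (g1 + 1) / (g1 + 1)
    d = np.empty_like(u)
    head = u <= F_L1
    d[head] = (u[head] * (g1 + 1) / C1) ** (1.0 / (g1 + 1))
    rest = ~head
    if abs(g2 + 1) < 1e-12:
        d[rest] = L1 * np.exp((u[rest] - F_L1) / C2)
    else:
        d[rest] = (
            L1 ** (g2 + 1) + (u[rest] - F_L1) * (g2 + 1) / C2
        ) ** (1.0 / (g2 + 1))
    return np.clip(d, 0.0, L2)


def sample_degree_lists(
    N: int, cfg: DegreeDistConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (in_degree, out_degree) lists from the Gaussian-copula-coupled
    truncated power-law marginals, rounded to integers."""
    from scipy.stats import norm

    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, cfg.rho], [cfg.rho, 1.0]], size=N
    )
    u = norm.cdf(z)
    d_in = np.rint(_powerlaw_ppf(u[:, 0], cfg))
    d_out = np.rint(_powerlaw_ppf(u[:, 1], cfg))
    return d_in, d_out


def make_degree_correlated(N: int, cfg: DegreeDistConfig, seed: int) -> np.ndarray:
    """Digraph with copula-correlated truncated power-law in/out degrees.

    Edge (i, j) (synapse j -> i) is an independent Bernoulli with likelihood
    proportional to in_degree(i) * out_degree(j), scaled so the expected total
    edge count is N * mean_degree.  Probabilities that exceed one after
    scaling are clipped, with a warning reporting the clipped fraction.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    rng = np.random.default_rng(seed)
    d_in, d_out = sample_degree_lists(N, cfg, rng)
    target_edges = N * cfg.mean_degree
    raw = np.outer(d_in, d_out)
    np.fill_diagonal(raw, 0.0)
    total = raw.sum()
    if total <= 0:
        raise ValueError("degenerate degree lists (all zero)")
    P = raw * (target_edges / total)
    n_over = int((P > 1.0).sum())
    if n_over:
        warnings.warn(
            f"clipped {n_over} edge probabilities > 1 "
            f"({n_over / N**2:.2%} of entries)",
            RuntimeWarning,
            stacklevel=2,
        )
        P = np.minimum(P, 1.0)
    W0 = (rng.random((N, N)) < P).astype(np.int8)
    np.fill_diagonal(W0, 0)
    return W0


# ---------------------------------------------------------------------------
# Motif statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifFrequencies:
    """Two-synapse motif frequencies of a binary adjacency matrix.

    All sums run over every index pair/triple (coincident indices included;
    the structurally zero diagonal removes autapse terms), with the chance
    level p0^2 subtracted from the q0 coordinates.
    """

    p0: float
    q0_div: float
    q0_con: float
    q0_ch: float
    q0_rec: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def motif_frequencies(W0: np.ndarray) -> MotifFrequencies:
    W0 = _validate_adjacency(W0).astype(float)
    N = W0.shape[0]
    p0 = W0.sum() / N**2
    out_deg = W0.sum(axis=0)   # column sums: outgoing edges of each neuron
    in_deg = W0.sum(axis=1)    # row sums: incoming edges
    q0_div = (out_deg @ out_deg) / N**3 - p0**2
    q0_con = (in_deg @ in_deg) / N**3 - p0**2
    q0_ch = (in_deg @ out_deg) / N**3 - p0**2
    q0_rec = float((W0 * W0.T).sum()) / N**2 - p0**2
    return MotifFrequencies(float(p0), float(q0_div), float(q0_con),
                            float(q0_ch), float(q0_rec))


@dataclass(frozen=True)
class MotifState:
    """Weighted motif coordinates on the epsilon-rescaled scale.

    ``q_ch = q_rec + q_op`` holds by construction.  ``q_div``/``q_con`` are
    (up to scale) the variances of weighted out-/in-degrees and so are
    nonnegative; ``q_ch`` is the corresponding covariance and can take either
    sign.  The qX coordinates are synapse strengths conditioned on membership
    in each binary motif; ``qX2_rec`` is the conditioned second moment of
    weights lying on disynaptic loops.
    """

    p: float
    q_div: float
    q_con: float
    q_ch: float
    q_rec: float
    q_op: float
    qX_rec: float
    qX_div: float
    qX_con: float
    qX_chA: float
    qX_chB: float
    qX2_rec: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MotifState":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))


def motif_strengths(net: WeightedNetwork) -> MotifState:
    """All twelve weighted/mixed motif coordinates of a network, exactly."""
    W = net.W
    W0 = net.W0.astype(float)
    N = net.N
    eps = net.epsilon
    p0 = net.p0

    in_w = W.sum(axis=1)       # weighted in-degrees
    out_w = W.sum(axis=0)      # weighted out-degrees
    in_d = W0.sum(axis=1)
    out_d = W0.sum(axis=0)

    p = W.sum() / (N**2 * eps)
    q_div = (out_w @ out_w) / (N**3 * eps**2) - p**2
    q_con = (in_w @ in_w) / (N**3 * eps**2) - p**2
    q_ch = (in_w @ out_w) / (N**3 * eps**2) - p**2
    q_rec = float((W * W.T).sum()) / (N**3 * eps**2)
    q_op = q_ch - q_rec

    qX_rec = float((W * W0.T).sum()) / (N**2 * eps) - p * p0
    qX_div = (out_w @ out_d) / (N**3 * eps) - p * p0
    qX_con = (in_w @ in_d) / (N**3 * eps) - p * p0
    qX_chA = (out_w @ in_d) / (N**3 * eps) - p * p0
    qX_chB = (out_d @ in_w) / (N**3 * eps) - p * p0
    qX2_rec = float((W**2 * W0.T).sum()) / (N**3 * eps**2)

    return MotifState(
        p=float(p), q_div=float(q_div), q_con=float(q_con), q_ch=float(q_ch),
        q_rec=float(q_rec), q_op=float(q_op), qX_rec=float(qX_rec),
        qX_div=float(qX_div), qX_con=float(qX_con), qX_chA=float(qX_chA),
        qX_chB=float(qX_chB), qX2_rec=float(qX2_rec),
    )
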