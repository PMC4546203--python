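"""Network spike-train cross-covariances from linear-response theory.

Writing G(omega) for the propagation matrix with entries
G_ij(omega) = A_i(omega) J(omega) W_ij  (J the exponential-synapse filter,
A_i the linear response of the postsynaptic neuron), the full covariance is

    C(omega) = (I - G)^(-1) C0(omega) (I - G)^(-H)

with C0 the diagonal matrix of baseline power spectra, and the length-one
path truncation keeps the terms G C0 + C0 G^H + G C0 G^H off the diagonal
(direct forward and backward connections plus common input).

Frequencies are cycles/ms under the exp(-2 pi i omega t) convention; the
kernels of real time series satisfy X(-omega) = conj(X(omega)), so only
omega >= 0 is ever solved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fokker_planck import FrequencyGrid, NeuronStatsTable
from .params import STDPRule, TAU_S_DEFAULT

__all__ = [
    "synaptic_filter",
    "CovarianceSet",
    "full_covariance",
    "truncated_covariance",
    "freq_to_time",
    "FrequencyQuadrature",
    "rule_weighted_integrals",
    "spectral_radius",
]


def synaptic_filter(omegas, tauS: float = TAU_S_DEFAULT) -> np.ndarray:
    """Fourier transform of the exponential synapse H(t) exp(-t/tauS)."""
    omegas = np.asarray(omegas, dtype=float)
    return tauS / (1.0 + 2j * np.pi * omegas * tauS)


def _propagator(W, A_col, Jw):
    """G(omega) = diag(A) W J for one frequency; A_col shape (N,)."""
    return (A_col * Jw)[:, None] * W


def spectral_radius(W, A_col, Jw, n_iter: int = 50, seed: int = 0) -> float:
    """Power-iteration estimate of the spectral radius of G(omega)."""
    N = W.shape[0]
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(N) + 1j * rng.standard_normal(N)
    v /= np.linalg.norm(v)
    lam = 0.0
    scale = A_col * Jw
    for _ in range(n_iter):
        w = scale * (W @ v)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 0.0
        lam = nrm
        v = w / nrm
    return float(lam)


@dataclass
class CovarianceSet:
    """Cross-covariances on a shared frequency grid (and lazily in time).

    ``C_omega`` has shape (n_omega, N, N) (dense) and satisfies
    C(-omega) = conj(C(omega)); only the frequencies in ``omegas`` are stored.
    """

    omegas: np.ndarray
    C_omega: np.ndarray
    flavor: str

    @property
    def N(self) -> int:
        return self.C_omega.shape[1]

    def time_domain(self, lags: np.ndarray, pairs=None):
        """Inverse transform onto a lag grid for the requested pairs."""
        return freq_to_time(self.omegas, self.C_omega, lags, pairs)

    def to_hdf5(self, path, group: str = "covariance") -> None:
        import h5py

        with h5py.File(path, "a") as f:
            g = f.require_group(group)
            for name in ("omegas", "C_real", "C_imag"):
                if name in g:
                    del g[name]
            g.create_dataset("omegas", data=self.omegas)
            g.create_dataset("C_real", data=self.C_omega.real)
            g.create_dataset("C_imag", data=self.C_omega.imag)
            g.attrs["flavor"] = self.flavor


def _stats_arrays(net, stats, omegas):
    """Per-neuron (A, C0) arrays of shape (N, n_omega) from a
    NeuronStatsTable + mu_eff, or from explicit arrays."""
    if isinstance(stats, tuple) and len(stats) == 2 and hasattr(stats[0], "A_matrix"):
        table, mu_eff = stats
        return table.A_matrix(mu_eff), table.C0_matrix(mu_eff)
    A, C0 = stats
    return np.asarray(A), np.asarray(C0)


def full_covariance(net, stats, omegas, tauS: float = TAU_S_DEFAULT,
                    check_stability: bool = True) -> CovarianceSet:
    """Dense solve of the full linear-response covariance at each frequency.

    ``stats`` is either (A, C0) arrays of shape (N, n_omega) or a
    (NeuronStatsTable, mu_eff) pair.  Raises RuntimeError when the spectral
    radius of G(0) reaches one (linearization invalid).
    """
    omegas = np.asarray(omegas, dtype=float)
    A, C0 = _stats_arrays(net, stats, omegas)
    W = net.W
    N = W.shape[0]
    Jw = synaptic_filter(omegas, tauS)
    if check_stability:
        k0 = int(np.argmin(np.abs(omegas)))
        rad = spectral_radius(W, A[:, k0], Jw[k0])
        if rad >= 1.0:
            raise RuntimeError(
                f"linearization invalid: spectral radius {rad:.3f} >= 1"
            )
    C = np.empty((omegas.size, N, N), complex)
    I = np.eye(N)
    for k in range(omegas.size):
        G = _propagator(W, A[:, k], Jw[k])
        M = I - G
        # (I-G)^{-1} C0 (I-G)^{-H} via two solves
        X = np.linalg.solve(M, np.diag(C0[:, k]).astype(complex))
        C[k] = np.linalg.solve(M, X.conj().T).conj().T
    return CovarianceSet(omegas=omegas, C_omega=C, flavor="full")


def truncated_covariance(net, stats, omegas, tauS: float = TAU_S_DEFAULT
                         ) -> CovarianceSet:
    """Length-one-path truncation: forward + backward + common-input terms,
    with the diagonal set to the baseline spectra."""
    omegas = np.asarray(omegas, dtype=float)
    A, C0 = _stats_arrays(net, stats, omegas)
    W = net.W
    N = W.shape[0]
    Jw = synaptic_filter(omegas, tauS)
    C = np.empty((omegas.size, N, N), complex)
    for k in range(omegas.size):
        G = _propagator(W, A[:, k], Jw[k])
        D = C0[:, k]
        GC = G * D[None, :]                 # G C0
        common = (G * D[None, :]) @ G.conj().T
        Ck = GC + GC.conj().T + common
        Ck[np.diag_indices(N)] = D
        C[k] = Ck
    return CovarianceSet(omegas=omegas, C_omega=C, flavor="truncated")


def freq_to_time(omegas, C_omega, lags, pairs=None, alias_tol: float = 0.01):
    """Inverse Fourier transform C(omega) -> C(s) on ``lags``.

    ``omegas`` must be a uniform symmetric grid.  Raises on aliasing (spectral
    energy at the grid edge above ``alias_tol`` of the peak for some pair) and
    discards imaginary residue after checking it is < 1e-8 of the maximum
    modulus.
    """
    omegas = np.asarray(omegas, dtype=float)
    lags = np.asarray(lags, dtype=float)
    d = np.diff(omegas)
    if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
        raise ValueError("frequency grid must be uniform for the transform")
    domega = d[0]
    if C_omega.ndim == 2:   # (n_omega, n_pairs)
        spec = C_omega
        squeeze = False
    elif C_omega.ndim == 1:
        spec = C_omega[:, None]
        squeeze = True
    else:
        if pairs is None:
            N = C_omega.shape[1]
            pairs = [(i, j) for i in range(N) for j in range(N)]
        spec = np.stack([C_omega[:, i, j] for (i, j) in pairs], axis=1)
        squeeze = False
    # aliasing check on the fluctuating part of each spectrum: the flat
    # high-frequency level of the diagonal spectra is the delta atom at s=0
    # and is allowed at the grid edge
    flat = 0.5 * (spec[0] + spec[-1])
    fluct = spec - flat[None, :]
    edge = np.abs(fluct[[0, -1]]).max(axis=0)
    peak = np.abs(fluct).max(axis=0)
    bad = edge > alias_tol * np.maximum(peak, 1e-300)
    if np.any(bad & (peak > 1e-12 * np.abs(spec).max())):
        raise ValueError("aliasing: spectral energy at the frequency-grid edge")
    # chunk over lags: the phase matrix for fine grids is otherwise huge
    Cs = np.empty((lags.size, spec.shape[1]), complex)
    step = max(1, int(2e7 // max(omegas.size, 1)))
    for a in range(0, lags.size, step):
        phase = np.exp(2j * np.pi * np.outer(lags[a:a + step], omegas))
        Cs[a:a + step] = phase @ spec * domega
    resid = np.abs(Cs.imag).max()
    scale = max(np.abs(Cs).max(), 1e-300)
    if resid > 1e-8 * scale:
        raise ValueError(f"imaginary residue {resid:.2e} too large")
    out = Cs.real
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# STDP-rule-weighted covariance integrals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyQuadrature:
    """Composite Gauss-Legendre quadrature on omega in (0, omega_max].

    Integrals of rule-weighted covariances over the whole line reduce to
    2 Re of the positive-frequency integral because the integrands are
    Fourier transforms of real functions.  Panels are geometric so the nodes
    concentrate where the STDP rule transform lives (|omega| < ~1/tau_minus).
    """

    nodes: np.ndarray
    weights: np.ndarray

    @classmethod
    def build(cls, omega_max: float = 1.0, n_per_panel: int = 10,
              n_panels: int = 9) -> "FrequencyQuadrature":
        edges = [0.0] + [omega_max * 2.0 ** (k - n_panels + 1)
                         for k in range(n_panels)]
        x, w = np.polynomial.legendre.leggauss(n_per_panel)
        nodes, weights = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            nodes.append(0.5 * (b - a) * x + 0.5 * (a + b))
            weights.append(0.5 * (b - a) * w)
        return cls(np.concatenate(nodes), np.concatenate(weights))

    def integrate(self, vals: np.ndarray) -> np.ndarray:
        """2 Re sum(w * vals) along the first axis."""
        return 2.0 * np.real(np.tensordot(self.weights, vals, axes=(0, 0)))


def rule_weighted_integrals(net, stats, rule: STDPRule,
                            flavor: str = "full",
                            tauS: float = TAU_S_DEFAULT,
                            quad: FrequencyQuadrature | None = None):
    """Matrices of int L±(s) C_ij(s) ds for every pair.

    Returns (X_plus, X_minus): the potentiation- and depression-window
    weighted covariance integrals (X = X_plus + X_minus equals the integral
    against the whole rule).  ``flavor`` selects the full solve or the
    length-one truncation.
    """
    if quad is None:
        quad = FrequencyQuadrature.build()
    omegas = quad.nodes
    if flavor == "full":
        cs = full_covariance(net, stats, omegas, tauS)
    elif flavor == "truncated":
        cs = truncated_covariance(net, stats, omegas, tauS)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    two_pi_i = 2j * np.pi * omegas
    Lp = rule.f_plus * rule.tau_plus / (1.0 + two_pi_i * rule.tau_plus)
    Lm = -rule.f_minus * rule.tau_minus / (1.0 - two_pi_i * rule.tau_minus)
    # int L C ds = int conj(L(omega)) C(omega) domega  (Plancherel)
    Xp = quad.integrate(np.conj(Lp)[:, None, None] * cs.C_omega)
    Xm = quad.integrate(np.conj(Lm)[:, None, None] * cs.C_omega)
    return Xp, Xm
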