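"""Fokker-Planck numerics for a single white-noise-driven EIF neuron.

The voltage SDE

    C dV = [gL (VL - V) + gL Delta exp((V - VT)/Delta) + mu] dt + gL sigma D dW

(D = sqrt(2 C / gL)) has diffusion coefficient B = gL sigma^2 / C in the
stationary Fokker-Planck equation.  All spectral quantities live under the
Fourier convention y(omega) = int y(t) exp(-2 pi i omega t) dt with omega in
cycles/ms (kHz).

Everything here is computed by threshold integration: a single backward sweep
of the probability flux/density pair from the numerical spike threshold Vth
down to an absorbing lower bound, with reinjection at the reset Vre.  The
sweep solves, at every requested frequency, three linear systems that combine
into

- the stationary firing rate r (with the refractory correction),
- the linear response A(omega) = rate modulation per unit current modulation,
- the first-passage-time density transform f(omega), from which the renewal
  power spectrum C0(omega) = r (1 - |f|^2)/|1 - f|^2 follows (the refractory
  period enters f as the pure delay exp(-2 pi i omega tau_ref)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import EIFParams

__all__ = [
    "FrequencyGrid",
    "SingleNeuronStats",
    "stationary_rate",
    "stationary_rate_vec",
    "linear_response",
    "power_spectrum",
    "compute_stats",
    "self_consistent_rates",
    "NeuronStatsTable",
]

_OMEGA_TINY = 1e-5  # kHz; stands in for omega = 0 where formulas are 0/0


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform symmetric frequency grid (cycles/ms) containing omega = 0."""

    domega: float
    n_half: int

    def __post_init__(self) -> None:
        if self.domega <= 0 or self.n_half < 1:
            raise ValueError("need domega > 0 and n_half >= 1")

    @classmethod
    def uniform(cls, domega: float = 1.0 / 512, omega_max: float = 1.0
                ) -> "FrequencyGrid":
        return cls(domega=domega, n_half=int(round(omega_max / domega)))

    @property
    def omegas(self) -> np.ndarray:
        return np.arange(-self.n_half, self.n_half + 1) * self.domega

    @property
    def positive(self) -> np.ndarray:
        return np.arange(0, self.n_half + 1) * self.domega

    @property
    def M(self) -> int:
        return 2 * self.n_half + 1

    def lag_grid(self) -> np.ndarray:
        """Natural conjugate lag grid: spacing 1/(M domega), span 1/(2 domega)."""
        ds = 1.0 / (self.M * self.domega)
        return (np.arange(self.M) - self.n_half) * ds


@dataclass
class SingleNeuronStats:
    """Stationary rate, linear response and baseline power spectrum at one
    operating point (mu_eff, sigma)."""

    r: float                 # spikes/ms
    A: np.ndarray            # complex, on ``omegas``
    C0: np.ndarray           # real >= 0, on ``omegas``
    omegas: np.ndarray
    mu_eff: float
    sigma: float


def _voltage_grid(eif: EIFParams, sigma: float, n_target: int
                  ) -> tuple[np.ndarray, int]:
    """Uniform grid from VL - 5 sigma to Vth with Vre exactly on it."""
    v_lb = min(eif.VL, eif.Vre) - 5.0 * sigma
    h = (eif.Vth - v_lb) / (n_target - 1)
    m_up = max(int(np.ceil((eif.Vth - eif.Vre) / h)), 2)
    h = (eif.Vth - eif.Vre) / m_up
    m_low = max(int(np.ceil((eif.Vre - v_lb) / h)), 1)
    V = eif.Vre + (np.arange(-(m_low), m_up + 1)) * h
    k_re = m_low
    return V, k_re


def _drift(V: np.ndarray, mu, eif: EIFParams):
    expo = np.exp(np.minimum((V - eif.VT) / eif.Delta, 60.0))
    return (eif.gL * (eif.VL - V) + eif.gL * eif.Delta * expo + mu) / eif.C


def _stationary_sweep(mu, sigma: float, eif: EIFParams, n_grid: int):
    """Backward sweep of the stationary system, vectorized over operating
    points.  Returns (V grid, k_re, free density p(V) per unit rate, rate)."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    V, k_re = _voltage_grid(eif, sigma, n_grid)
    h = V[1] - V[0]
    B = eif.gL * sigma**2 / eif.C
    n = V.size
    Vm = 0.5 * (V[1:] + V[:-1])
    F = _drift(Vm[:, None], mu[None, :], eif)          # (n-1, n_mu)
    a = F / B
    p = np.zeros((n, mu.size))
    for k in range(n - 1, 0, -1):
        j = 1.0 if k - 1 >= k_re else 0.0
        ah = a[k - 1] * h
        eah = np.exp(np.clip(-ah, None, 700.0))
        # dp/dV = a p + b with b = -j/B; exact step for frozen coefficients
        with np.errstate(divide="ignore", invalid="ignore"):
            incr = np.where(
                np.abs(ah) > 1e-8,
                (j / F[k - 1]) * (1.0 - eah),
                j * h / B * (1.0 - 0.5 * ah),
            )
        # clamp: in deeply subthreshold/low-noise regimes the scaled density
        # 1/r overflows; clamping just pins the rate at (numerically) zero
        p[k - 1] = np.minimum(p[k] * eah + incr, 1e250)
        if np.any(np.isnan(p[k - 1])):
            raise FloatingPointError(
                "stationary Fokker-Planck sweep diverged; "
                f"grid n={n}, h={h:.3g} mV, sigma={sigma}"
            )
    T_free = np.trapezoid(p, dx=h, axis=0)
    r = 1.0 / (T_free + eif.tau_ref)
    return V, k_re, p, r


def stationary_rate(mu: float, sigma: float, eif: EIFParams,
                    n_grid: int = 3000) -> float:
    """Stationary EIF firing rate (spikes/ms) at input mean ``mu``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(_stationary_sweep(mu, sigma, eif, n_grid)[3][0])


def stationary_rate_vec(mu, sigma: float, eif: EIFParams,
                        n_grid: int = 3000) -> np.ndarray:
    """Vectorized stationary rate over an array of input means."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return _stationary_sweep(mu, sigma, eif, n_grid)[3]


def _spectral_sweep(mu: float, sigma: float, eif: EIFParams,
                    omegas: np.ndarray, n_grid: int):
    """One backward sweep solving the three frequency-domain systems at all
    ``omegas`` (> 0) simultaneously.

    Returns (r, A(omega), f_isi(omega)) where f_isi includes the refractory
    delay factor.
    """
    V, k_re, p_st, r_arr = _stationary_sweep(mu, sigma, eif, n_grid)
    r = float(r_arr[0])
    P0 = r * p_st[:, 0]
    h = V[1] - V[0]
    B = eif.gL * sigma**2 / eif.C
    n = V.size
    Vm = 0.5 * (V[1:] + V[:-1])
    F = _drift(Vm, mu, eif)
    a = F / B
    iw = 2j * np.pi * omegas          # (n_w,)
    delay = np.exp(-iw * eif.tau_ref)

    n_w = omegas.size
    jh = np.ones(n_w, complex)
    ph = np.zeros(n_w, complex)
    js = np.zeros(n_w, complex)
    ps = np.zeros(n_w, complex)
    jE = np.zeros(n_w, complex)
    pE = np.zeros(n_w, complex)

    for k in range(n - 1, 0, -1):
        ah = a[k - 1] * h
        eah = np.exp(-ah)
        if abs(ah) > 1e-8:
            g = (1.0 - eah) / a[k - 1]      # integrates constant forcing
        else:
            g = h * (1.0 - 0.5 * ah)
        # p step: dp/dV = a p + b  =>  p(V-h) = p e^{-ah} - (b/a)(1 - e^{-ah})
        bh = -jh / B
        bs = -js / B
        bE = (-jE + 0.5 * (P0[k] + P0[k - 1]) / eif.C) / B
        ph_new = ph * eah - bh * g
        ps_new = ps * eah - bs * g
        pE_new = pE * eah - bE * g
        # j step (trapezoid): dj/dV = -2 pi i w p  =>  j(V-h) = j + h iw <p>
        jh = jh + 0.5 * h * iw * (ph + ph_new)
        js = js + 0.5 * h * iw * (ps + ps_new)
        jE = jE + 0.5 * h * iw * (pE + pE_new)
        ph, ps, pE = ph_new, ps_new, pE_new
        if k - 1 == k_re:
            js = js - 1.0   # unit injection at the reset potential
    denom = jh + delay * js
    A = -jE / denom
    f0 = -js / jh
    return r, A, f0 * delay


def _split_omegas(omegas: np.ndarray):
    """Map an arbitrary frequency array onto strictly positive evaluation
    frequencies, replacing 0 by a tiny positive frequency."""
    omegas = np.asarray(omegas, dtype=float)
    ev = np.abs(omegas)
    ev[ev < _OMEGA_TINY] = _OMEGA_TINY
    return ev


def compute_stats(mu: float, sigma: float, eif: EIFParams, omegas,
                  n_grid: int = 3000) -> SingleNeuronStats:
    """Rate, linear response and power spectrum at one operating point.

    ``omegas`` may be any array of frequencies (cycles/ms); negative
    frequencies are filled by Hermitian symmetry A(-w) = conj(A(w)),
    C0(-w) = C0(w).
    """
    omegas = np.asarray(omegas, dtype=float)
    ev = _split_omegas(omegas)
    uniq, inv = np.unique(ev, return_inverse=True)
    r, A_u, f_u = _spectral_sweep(mu, sigma, eif, uniq, n_grid)
    A = A_u[inv]
    f = f_u[inv]
    # A(0) is real (it is dr/dmu); drop the residue of the tiny-omega proxy
    zero = np.abs(omegas) < _OMEGA_TINY
    A[zero] = A[zero].real
    neg = omegas < 0
    A[neg] = np.conj(A[neg])
    with np.errstate(divide="ignore", invalid="ignore"):
        C0 = r * (1.0 - np.abs(f) ** 2) / np.abs(1.0 - f) ** 2
    C0 = np.maximum(np.real(C0), 0.0)
    return SingleNeuronStats(r=r, A=A, C0=C0, omegas=omegas,
                             mu_eff=float(mu), sigma=float(sigma))


def linear_response(mu: float, sigma: float, eif: EIFParams, omegas,
                    n_grid: int = 3000) -> np.ndarray:
    """Complex linear response A(omega) (rate per unit current)."""
    return compute_stats(mu, sigma, eif, omegas, n_grid).A


def power_spectrum(mu: float, sigma: float, eif: EIFParams, omegas,
                   n_grid: int = 3000) -> np.ndarray:
    """Baseline spike-train power spectrum C0(omega) (spikes^2/ms)."""
    return compute_stats(mu, sigma, eif, omegas, n_grid).C0


# ---------------------------------------------------------------------------
# Network-level self-consistent rates
# ---------------------------------------------------------------------------

def self_consistent_rates(net, mu: float, sigma: float, eif: EIFParams,
                          tauS: float, tol: float = 1e-6,
                          max_iter: int = 500, n_grid: int = 3000,
                          damping: float = 0.5):
    """Fixed point of r_i = r(mu + tauS * sum_j W_ij r_j, sigma).

    Returns (rates, mu_eff).  Raises RuntimeError on rate instability
    (non-convergence within ``max_iter`` damped iterations).
    """
    W = net.W
    N = W.shape[0]
    r = np.full(N, stationary_rate(mu, sigma, eif, n_grid))
    for _ in range(max_iter):
        mu_eff = mu + tauS * (W @ r)
        r_new = stationary_rate_vec(mu_eff, sigma, eif, n_grid)
        delta = np.max(np.abs(r_new - r))
        r = damping * r + (1.0 - damping) * r_new
        if delta < tol:
            mu_eff = mu + tauS * (W @ r)
            return r, mu_eff
    raise RuntimeError(
        "rate instability: self-consistent rate iteration did not converge"
    )


class NeuronStatsTable:
    """Linear-interpolation table of single-neuron statistics over mu_eff.

    Computing A(omega) and C0(omega) exactly for every neuron is wasteful when
    the effective means span a narrow range; the table evaluates the
    threshold-integration solve at ``n_nodes`` equally spaced operating points
    covering [min mu_eff, max mu_eff] and interpolates linearly in mu.
    """

    def __init__(self, mu_eff: np.ndarray, sigma: float, eif: EIFParams,
                 omegas, n_nodes: int = 7, n_grid: int = 3000):
        mu_eff = np.asarray(mu_eff, dtype=float)
        lo, hi = float(mu_eff.min()), float(mu_eff.max())
        if hi - lo < 1e-9:
            nodes = np.array([lo])
        else:
            nodes = np.linspace(lo, hi, n_nodes)
        stats = [compute_stats(m, sigma, eif, omegas, n_grid) for m in nodes]
        self.nodes = nodes
        self.omegas = np.asarray(omegas, dtype=float)
        self._r = np.array([s.r for s in stats])
        self._A = np.array([s.A for s in stats])      # (n_nodes, n_w)
        self._C0 = np.array([s.C0 for s in stats])
        self.sigma = sigma

    def _weights(self, mu: np.ndarray):
        nodes = self.nodes
        if nodes.size == 1:
            idx = np.zeros(mu.shape, int)
            return idx, idx, np.zeros(mu.shape)
        i = np.clip(np.searchsorted(nodes, mu) - 1, 0, nodes.size - 2)
        t = (mu - nodes[i]) / (nodes[i + 1] - nodes[i])
        return i, i + 1, np.clip(t, 0.0, 1.0)

    def rates(self, mu_eff) -> np.ndarray:
        mu = np.asarray(mu_eff, dtype=float)
        i, j, t = self._weights(mu)
        return (1 - t) * self._r[i] + t * self._r[j]

    def A_matrix(self, mu_eff) -> np.ndarray:
        """(n_neurons, n_omega) linear responses."""
        mu = np.asarray(mu_eff, dtype=float)
        i, j, t = self._weights(mu)
        return (1 - t)[:, None] * self._A[i] + t[:, None] * self._A[j]

    def C0_matrix(self, mu_eff) -> np.ndarray:
        mu = np.asarray(mu_eff, dtype=float)
        i, j, t = self._weights(mu)
        return (1 - t)[:, None] * self._C0[i] + t[:, None] * self._C0[j]
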