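"""Reduced dynamics of two-synapse motifs under STDP.

The high-dimensional weight evolution collapses, via (i) the length-one-path
truncation of spiking covariances, (ii) dropping the weight bounds, and
(iii) re-summing three- and four-synapse motifs as products of one- and
two-synapse motifs, to an autonomous ODE system for the mean weight p, the
motif strengths q^div, q^con, q^ch (split as q^ch = q^rec + q^op), and the
mixed motifs qX that condition synapse strength on motif membership.

Four scalars collapse the interaction of the STDP rule L(s) with spiking
covariance, evaluated at a frozen operating point (mean weight p0 wmax / 2):

    S   = int L(s) ds                       (chance coincidences)
    S_F = int L(s) (K * C0)(s) ds           (forward connections)
    S_B = int L(s) (C0 * K^-)(s) ds         (backward connections)
    S_C = int L(s) (K * C0 * K^-)(s) ds     (common input)

with K(t) = A(t) * J(t) the rate-response kernel and C0 the baseline
autocovariance.  For Hebbian rules with f+ > f-, tau+ < tau-: S_F > 0,
S_B < 0, S_C > 0.  All amplitudes here are on the *unscaled* weight scale;
the mean in-degree scaling epsilon = 1/(N p0) appears explicitly in the
equations, and p ranges over [0, p0 wmax].
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import EIFParams, NoiseParams, STDPRule, TAU_S_DEFAULT
from .fokker_planck import SingleNeuronStats, compute_stats, stationary_rate
from .covariance import FrequencyQuadrature, synaptic_filter
from .network import MotifFrequencies, MotifState

__all__ = [
    "STDPIntegrals",
    "MotifODEConfig",
    "frozen_operating_point",
    "stdp_integrals",
    "motif_rhs",
    "integrate_motifs",
    "unbalanced_solution",
    "mean_weight_fixed_points",
    "state_to_vector",
    "vector_to_state",
]

_COORDS = ["p", "q_div", "q_con", "q_ch", "q_rec", "qX2_rec",
           "qX_rec", "qX_div", "qX_con", "qX_chA", "qX_chB"]


@dataclass(frozen=True)
class STDPIntegrals:
    """Rule-covariance overlap scalars at a frozen operating point."""

    S: float        # weight * ms
    S_F: float
    S_B: float
    S_C: float
    r: float        # network-mean stationary rate, spikes/ms
    mu_eff: float

    def asserted_hebbian(self) -> "STDPIntegrals":
        if not (self.S_F > 0 and self.S_B < 0 and self.S_C > 0):
            raise ValueError(
                f"expected S_F > 0 > S_B and S_C > 0 for a Hebbian rule; got "
                f"S_F={self.S_F:.3g}, S_B={self.S_B:.3g}, S_C={self.S_C:.3g}"
            )
        return self


@dataclass(frozen=True)
class MotifODEConfig:
    """Frozen baseline structure entering the reduced system."""

    p0: float
    q0_div: float
    q0_con: float
    q0_ch: float
    q0_rec: float
    epsilon: float
    rtol: float = 1e-8
    atol: float = 1e-12

    @classmethod
    def from_frequencies(cls, freqs: MotifFrequencies, N: int, **kw
                         ) -> "MotifODEConfig":
        return cls(p0=freqs.p0, q0_div=freqs.q0_div, q0_con=freqs.q0_con,
                   q0_ch=freqs.q0_ch, q0_rec=freqs.q0_rec,
                   epsilon=1.0 / (N * freqs.p0), **kw)


def frozen_operating_point(
    p0: float, wmax: float, noise: NoiseParams, eif: EIFParams,
    tauS: float = TAU_S_DEFAULT, fill: float = 0.5,
) -> tuple[float, float]:
    """Self-consistent (rate, mu_eff) of the homogeneous network at mean
    weight p = fill * p0 * wmax (wmax on the unscaled scale)."""
    w_bar = fill * wmax     # = p / p0

    def gap(r):
        return stationary_rate(noise.mu + tauS * w_bar * r, noise.sigma, eif) - r

    r_hi = stationary_rate(noise.mu, noise.sigma, eif)
    # bracket upward until the net input stabilizes
    hi = max(2.0 * r_hi, 1e-3)
    for _ in range(60):
        if gap(hi) < 0:
            break
        hi *= 1.5
    else:
        raise RuntimeError("rate instability: no self-consistent rate")
    r = brentq(gap, 0.0, hi, xtol=1e-12)
    return r, noise.mu + tauS * w_bar * r


def stdp_integrals(
    rule: STDPRule,
    stats: SingleNeuronStats | None = None,
    tauS: float = TAU_S_DEFAULT,
    quad: FrequencyQuadrature | None = None,
    *,
    p0: float | None = None,
    noise: NoiseParams | None = None,
    eif: EIFParams | None = None,
    fill: float = 0.5,
) -> STDPIntegrals:
    """Compute (S, S_F, S_B, S_C, r) for a rule on the unscaled weight scale.

    Either pass precomputed ``stats`` (on the quadrature nodes) or the
    (p0, noise, eif) triple to solve the frozen operating point here.
    """
    if quad is None:
        quad = FrequencyQuadrature.build()
    if stats is None:
        if p0 is None or noise is None or eif is None:
            raise ValueError("need stats or (p0, noise, eif)")
        r, mu_eff = frozen_operating_point(p0, rule.wmax, noise, eif, tauS,
                                           fill)
        stats = compute_stats(mu_eff, noise.sigma, eif, quad.nodes)
    omegas = stats.omegas
    K = stats.A * synaptic_filter(omegas, tauS)
    C0 = stats.C0
    L = rule.L_fourier(omegas)
    S_F = float(quad.integrate(np.conj(L) * K * C0))
    S_B = float(quad.integrate(np.conj(L) * C0 * np.conj(K)))
    S_C = float(quad.integrate(np.conj(L) * np.abs(K) ** 2 * C0))
    return STDPIntegrals(S=rule.S, S_F=S_F, S_B=S_B, S_C=S_C,
                         r=stats.r, mu_eff=stats.mu_eff)


# ---------------------------------------------------------------------------
# The closed ODE system
# ---------------------------------------------------------------------------

def state_to_vector(state: MotifState) -> np.ndarray:
    d = state.as_dict()
    return np.array([d[k] for k in _COORDS])


def vector_to_state(y: np.ndarray) -> MotifState:
    d = dict(zip(_COORDS, (float(v) for v in y)))
    d["q_op"] = d["q_ch"] - d["q_rec"]
    return MotifState(**d)


def motif_rhs(y: np.ndarray, cfg: MotifODEConfig, ints: STDPIntegrals
              ) -> np.ndarray:
    """Time derivative (per ms) of the 11 motif coordinates."""
    (p, qdiv, qcon, qch, qrec, qX2, qXr, qXd, qXc, qXa, qXb) = y
    p0, eps = cfg.p0, cfg.epsilon
    q0d, q0c, q0ch, q0r = cfg.q0_div, cfg.q0_con, cfg.q0_ch, cfg.q0_rec
    S, SF, SB, SC, r = ints.S, ints.S_F, ints.S_B, ints.S_C, ints.r
    r2S = r * r * S
    pp0 = p * p0
    dv = qdiv + p * p

    dp = p0 * r2S + eps * (
        p * SF + (qXr + pp0) * SB
        + (p0 * dv + p * (qXc + qXb)) * SC / p0
    )
    dqdiv = 2 * r2S * qXd + 2 * eps * (
        qdiv * SF + (p0 * qch + p * qXd) * SB
        + (qch * (qXc + pp0) + qXd * dv) * SC / p0
    )
    dqcon = 2 * r2S * qXc + 2 * eps * (
        qcon * SF + (p0 * qch + p * qXc) * SB
        + (qcon * (qXb + pp0) + qXc * dv) * SC / p0
    )
    dqch = r2S * (qXa + qXb) + eps * (
        2 * qch * SF + (p0 * (qcon + qdiv) + p * (qXa + qXb)) * SB
        + (dv * (qXa + qXb) + qch * (qXb + pp0) + qcon * (qXc + pp0)) * SC / p0
    )
    dqrec = 2 * eps * (r2S * p0 * (qXr + pp0) + SF * qrec + SB * qX2)
    dqX2 = 2 * eps * (r2S * p0 * (qXr + pp0) + SF * qX2 + SB * qrec)
    dqXr = r2S * q0r + eps * (
        qXr * SF + (1 - p0) * (qXr + pp0) * SB
        + (q0r * dv + qXb * (qXb + pp0) + qXc * (qXc + pp0)) * SC / p0
    )
    dqXd = r2S * q0d + eps * (
        qXd * SF + (p * q0d + p0 * qXb) * SB
        + (q0d * dv + qXb * (qXc + pp0)) * SC / p0
    )
    dqXc = r2S * q0c + eps * (
        qXc * SF + (p * q0c + p0 * qXa) * SB
        + (q0c * dv + qXc * (qXb + pp0)) * SC / p0
    )
    dqXa = r2S * q0ch + eps * (
        qXa * SF + (p * q0ch + p0 * qXc) * SB
        + (q0ch * dv + qXc * (qXc + pp0)) * SC / p0
    )
    dqXb = r2S * q0ch + eps * (
        qXb * SF + (p * q0ch + p0 * qXd) * SB
        + (q0ch * dv + qXb * (qXb + pp0)) * SC / p0
    )
    return np.array([dp, dqdiv, dqcon, dqch, dqrec, dqX2,
                     dqXr, dqXd, dqXc, dqXa, dqXb])


def integrate_motifs(
    state0: MotifState, cfg: MotifODEConfig, ints: STDPIntegrals,
    T: float, n_out: int = 201, wmax: float | None = None,
):
    """Adaptive integration of the reduced system over T seconds.

    Returns (times_s, states, flags) where ``flags['p_out_of_bounds']`` marks
    trajectories whose mean weight left [0, p0 wmax] (the reduced system
    carries no weight bounds by construction).
    """
    y0 = state_to_vector(state0)
    T_ms = T * 1000.0
    sol = solve_ivp(
        lambda t, y: motif_rhs(y, cfg, ints),
        (0.0, T_ms), y0, method="RK45",
        t_eval=np.linspace(0.0, T_ms, n_out),
        rtol=cfg.rtol, atol=cfg.atol,
    )
    if not sol.success:
        raise RuntimeError(f"motif ODE integration failed: {sol.message}")
    states = [vector_to_state(sol.y[:, k]) for k in range(sol.t.size)]
    flags = {}
    if wmax is not None:
        p_traj = sol.y[0]
        flags["p_out_of_bounds"] = bool(
            np.any((p_traj < 0) | (p_traj > cfg.p0 * wmax))
        )
    return sol.t / 1000.0, states, flags


def unbalanced_solution(t_ms, state0: MotifState, cfg: MotifODEConfig,
                        ints: STDPIntegrals) -> MotifState:
    """Closed-form leading-order solution when |S| dominates the eps terms.

    Integrating dq/dt = 2 r^2 S qX, dqX/dt = r^2 S q0 (and the chain variant
    driven by qX_chA + qX_chB) exactly: p grows linearly at p0 r^2 S; each
    motif strength picks up a linear term from its mixed motif and a
    quadratic term q0 (r^2 S t)^2 from the baseline frequency - proportional
    to S^2, hence expansive for either sign of S; each mixed motif grows
    linearly from the baseline frequency.
    """
    r2S = ints.r**2 * ints.S
    d0 = state0.as_dict()

    def q_alpha(q0_alpha, q_init, qX_init):
        return q_init + 2.0 * qX_init * r2S * t_ms \
            + q0_alpha * r2S**2 * t_ms**2

    p = cfg.p0 * r2S * t_ms + d0["p"]
    out = dict(
        p=p,
        q_div=q_alpha(cfg.q0_div, d0["q_div"], d0["qX_div"]),
        q_con=q_alpha(cfg.q0_con, d0["q_con"], d0["qX_con"]),
        q_ch=d0["q_ch"] + (d0["qX_chA"] + d0["qX_chB"]) * r2S * t_ms
        + cfg.q0_ch * r2S**2 * t_ms**2,
        qX_rec=r2S * cfg.q0_rec * t_ms + d0["qX_rec"],
        qX_div=r2S * cfg.q0_div * t_ms + d0["qX_div"],
        qX_con=r2S * cfg.q0_con * t_ms + d0["qX_con"],
        qX_chA=r2S * cfg.q0_ch * t_ms + d0["qX_chA"],
        qX_chB=r2S * cfg.q0_ch * t_ms + d0["qX_chB"],
        q_rec=d0["q_rec"],
        qX2_rec=d0["qX2_rec"],
    )
    out["q_op"] = out["q_ch"] - out["q_rec"]
    return MotifState(**out)


def nullcline_scan(
    state0: MotifState, cfg: MotifODEConfig, ints: STDPIntegrals,
    plane: tuple[str, str], x_range, y_range, n: int = 41,
):
    """Sign of the two plane coordinates' derivatives on a grid.

    All coordinates other than the two in ``plane`` are frozen at
    ``state0``; the returned records (x, y, dx/dt, dy/dt and their signs)
    reconstruct nullcline projections and flow directions in that slice of
    the motif space.
    """
    import pandas as pd

    ix = _COORDS.index(plane[0])
    iy = _COORDS.index(plane[1])
    y0 = state_to_vector(state0)
    rows = []
    for x in np.linspace(*x_range, n):
        for yv in np.linspace(*y_range, n):
            y = y0.copy()
            y[ix], y[iy] = x, yv
            d = motif_rhs(y, cfg, ints)
            rows.append({plane[0]: x, plane[1]: yv,
                         f"d_{plane[0]}": d[ix], f"d_{plane[1]}": d[iy],
                         f"sign_{plane[0]}": int(np.sign(d[ix])),
                         f"sign_{plane[1]}": int(np.sign(d[iy]))})
    return pd.DataFrame(rows)


def mean_weight_fixed_points(cfg: MotifODEConfig, ints: STDPIntegrals):
    """Roots of the unstructured mean-weight dynamics
    p0 r^2 S / eps + p (S_F + p0 S_B) + p^2 S_C = 0, with stability labels.

    The balanced regime writes S = +/- delta * eps; dividing the invariant-set
    dynamics by eps leaves the quadratic above.  Returns a list of
    (p_root, 'stable'|'unstable') sorted by root value, or [] when the roots
    are complex.
    """
    if ints.S_C == 0:
        raise ValueError("S_C must be nonzero")
    a = ints.S_C
    b = ints.S_F + cfg.p0 * ints.S_B
    c = cfg.p0 * ints.r**2 * ints.S / cfg.epsilon
    disc = b * b - 4 * a * c
    if disc < 0:
        return []
    roots = sorted([(-b - np.sqrt(disc)) / (2 * a),
                    (-b + np.sqrt(disc)) / (2 * a)])
    out = []
    for p_star in roots:
        slope = b + 2 * a * p_star
        out.append((float(p_star), "stable" if slope < 0 else "unstable"))
    return out
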