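"""Model parameter containers.

All quantities are in the units used throughout the package: time in ms,
voltage in mV, currents in uA/cm^2, conductances in mS/cm^2, capacitance in
uF/cm^2, rates in spikes/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class EIFParams:
    """Exponential integrate-and-fire membrane parameters.

    The membrane voltage obeys

        C dV/dt = gL (VL - V) + gL * Delta * exp((V - VT)/Delta) + I(t) + Isyn

    A spike is registered when V crosses ``Vth``; the voltage is reset to
    ``Vre`` and held for ``tau_ref``.
    """

    C: float = 1.0          # membrane capacitance, uF/cm^2
    gL: float = 0.1         # leak conductance, mS/cm^2
    VL: float = -72.0       # leak reversal, mV
    Delta: float = 1.4      # spike steepness, mV
    VT: float = -48.0       # spike initiation threshold, mV
    Vth: float = 30.0       # numerical spike threshold, mV
    Vre: float = -72.0      # reset, mV
    tau_ref: float = 2.0    # absolute refractory period, ms

    def __post_init__(self) -> None:
        if not (self.Vre < self.VT < self.Vth):
            raise ValueError("require Vre < VT < Vth")
        if self.Delta <= 0:
            raise ValueError("Delta must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be nonnegative")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C/gL (ms)."""
        return self.C / self.gL


@dataclass(frozen=True)
class NoiseParams:
    """External input: I(t) = mu + gL * sigma * D * xi(t).

    ``D = sqrt(2 C / gL)`` (units sqrt(ms)) scales the white noise so that the
    stationary standard deviation of the passive membrane voltage equals
    ``sigma`` independently of the membrane time constant.  A fraction ``c``
    of the noise is shared between all neurons: the private and common terms
    mix with amplitudes sqrt(1-c) and sqrt(c).  The common term is either
    white noise (same intensity convention as the private term) or an
    Ornstein-Uhlenbeck process with timescale ``ou_tau`` and unit stationary
    variance, which concentrates the shared fluctuations below ~1/ou_tau and
    produces a visible central peak in pairwise spike covariances.
    """

    mu: float = 1.0          # mean input current, uA/cm^2
    sigma: float = 9.0       # noise strength, mV
    c: float = 0.0           # common-input fraction in [0, 1]
    common_kind: str = "white"   # "white" | "OU"
    ou_tau: float = 5.0      # OU timescale, ms

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")
        if self.common_kind not in ("white", "OU"):
            raise ValueError("common_kind must be 'white' or 'OU'")

    def D(self, eif: EIFParams) -> float:
        import math

        return math.sqrt(2.0 * eif.C / eif.gL)


@dataclass(frozen=True)
class STDPRule:
    """Additive, all-to-all pair-based Hebbian STDP rule.

    For a pre/post spike pair with lag s = t_post - t_pre the weight changes by

        L(s) = H(wmax - W) * f_plus  * exp(-|s|/tau_plus),   s >= 0
        L(s) = H(W)       * (-f_minus) * exp(-|s|/tau_minus), s < 0

    with hard bounds 0 <= W <= wmax.  Amplitudes ``f_plus``/``f_minus`` are on
    the same (possibly 1/(N p0)-rescaled) scale as the weights they modify.
    """

    f_plus: float
    f_minus: float
    tau_plus: float = 20.0
    tau_minus: float = 40.0
    wmax: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("tau_plus and tau_minus must be positive")
        if self.f_plus < 0 or self.f_minus < 0:
            raise ValueError("f_plus and f_minus must be nonnegative")

    @property
    def S(self) -> float:
        """Integral of the rule, f+ tau+ - f- tau- (weight * ms)."""
        return self.f_plus * self.tau_plus - self.f_minus * self.tau_minus

    def scaled(self, factor: float) -> "STDPRule":
        """Rule with amplitudes (and wmax) multiplied by ``factor``."""
        return replace(
            self,
            f_plus=self.f_plus * factor,
            f_minus=self.f_minus * factor,
            wmax=self.wmax * factor,
        )

    def L(self, s):
        """Evaluate the rule (without the bound factors) at lag(s) s."""
        import numpy as np

        s = np.asarray(s, dtype=float)
        pot = self.f_plus * np.exp(-np.abs(s) / self.tau_plus)
        dep = -self.f_minus * np.exp(-np.abs(s) / self.tau_minus)
        return np.where(s >= 0, pot, dep)

    def L_fourier(self, omega):
        """Fourier transform of L(s) under the exp(-2*pi*i*omega*s) convention."""
        import numpy as np

        omega = np.asarray(omega, dtype=float)
        two_pi_i = 2j * np.pi * omega
        pot = self.f_plus * self.tau_plus / (1.0 + two_pi_i * self.tau_plus)
        dep = -self.f_minus * self.tau_minus / (1.0 - two_pi_i * self.tau_minus)
        return pot + dep


def hebbian_rule(
    f_plus: float = 0.1,
    tau_plus: float = 20.0,
    tau_minus: float = 40.0,
    wmax: float = 5.0,
    balance: str = "depression",
    delta: float = 0.1,
    epsilon: float = 1.0,
) -> STDPRule:
    """Build a Hebbian rule from a balance condition.

    ``balance`` selects how the depression area f- tau- relates to the
    potentiation area f+ tau+:

    - "depression": balanced, tilted toward depression, S = -delta*epsilon*f+tau+
    - "potentiation": balanced, tilted toward potentiation, S = +delta*epsilon*f+tau+
    - "depression_x2": unbalanced, f- tau- = 2 f+ tau+  (S = -f+ tau+)
    - "potentiation_x2": unbalanced, f- tau- = f+ tau+ / 2  (S = +f+ tau+/2)
    - "exact": S = 0

    The imbalance parameter ``delta`` is applied on the scale of the
    potentiation area (relative convention), multiplied by ``epsilon``.
    Amplitudes are on whatever weight scale ``f_plus``/``wmax`` are given in.
    """
    area_plus = f_plus * tau_plus
    if balance == "depression":
        area_minus = area_plus * (1.0 + delta * epsilon)
    elif balance == "potentiation":
        area_minus = area_plus * (1.0 - delta * epsilon)
    elif balance == "depression_x2":
        area_minus = 2.0 * area_plus
    elif balance == "potentiation_x2":
        area_minus = 0.5 * area_plus
    elif balance == "exact":
        area_minus = area_plus
    else:
        raise ValueError(f"unknown balance {balance!r}")
    return STDPRule(
        f_plus=f_plus,
        f_minus=area_minus / tau_minus,
        tau_plus=tau_plus,
        tau_minus=tau_minus,
        wmax=wmax,
    )


@dataclass(frozen=True)
class SimConfig:
    """Simulation control for the spiking network integrator."""

    dt: float = 0.05             # Euler-Maruyama step, ms
    T: float = 10_000.0          # total simulated time, ms
    seed: int = 0
    plasticity_on: bool = False
    record_weights_every: float = 1_000.0   # ms; <= 0 disables snapshots
    record_spikes: bool = True
    rate_cap: float = 0.2        # abort threshold on mean network rate, spikes/ms

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < self.dt:
            raise ValueError("T must be at least dt")


@dataclass(frozen=True)
class DegreeDistConfig:
    """Correlated truncated power-law degree distribution.

    The in/out-degree marginal density is C1*d^gamma1 on [0, L1] and
    C2*d^gamma2 on [L1, L2], continuous at L1 and normalized; the two marginals
    are coupled by a Gaussian copula with correlation ``rho``.
    """

    gamma1: float = 0.2
    gamma2: float = -1.0
    L1: float = 100.0
    L2: float = 1000.0
    rho: float = 0.0
    mean_degree: float = 150.0   # target realized mean degree, N * p0

    def __post_init__(self) -> None:
        if not (0 <= self.L1 <= self.L2):
            raise ValueError("require 0 <= L1 <= L2")
        if not abs(self.rho) < 1:
            raise ValueError("require |rho| < 1")


TAU_S_DEFAULT = 5.0   # synaptic decay time constant, ms (exponential synapses)
P0_DEFAULT = 0.15
N_DEFAULT = 1000
WMAX_DEFAULT = 5.0
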