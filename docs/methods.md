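# Methods

This note records the model, the numerical choices, and the design decisions
behind `motifstdp`, at the level of detail a user needs to judge what the
package computes and what its tests do and do not establish.

## Model

**Neurons.** N exponential integrate-and-fire (EIF) neurons,

C dV_i/dt = gL (VL − V_i) + gL Δ exp((V_i − VT)/Δ) + I_i(t) + Σ_j W_ij (J∗y_j)(t),

with spikes thresholded at Vth, reset to Vre, and an absolute refractory
period τ_ref.  Defaults: C = 1 µF/cm², gL = 0.1 mS/cm², VL = Vre = −72 mV,
Δ = 1.4 mV, VT = −48 mV, Vth = 30 mV, τ_ref = 2 ms.  Synapses are
current-based exponentials J(t) = H(t) e^(−t/τS), τS = 5 ms, with peak
amplitude W_ij (µA/cm²) for the synapse j→i (matrix orientation throughout:
**row = postsynaptic, column = presynaptic**).

**Input.** I_i(t) = µ + gL σ D ξ_i(t) with µ = 1 µA/cm², σ = 9 mV and
D = √(2C/gL), so that the stationary standard deviation of the passive
membrane voltage is σ regardless of the membrane time constant.  A fraction
c of the noise can be shared: the private and common terms mix with
amplitudes √(1−c) and √c.  The common term is either white (same intensity
convention as the private noise) or an Ornstein–Uhlenbeck process with
timescale τ_OU (default 5 ms) and **unit stationary variance**.  The OU
normalization is a deliberate choice: it concentrates the shared power below
~1/τ_OU and produces the central covariance peak that drives joint
potentiation of reciprocal pairs; a spectral-density-matched OU (variance
1/(2τ_OU)) is an order of magnitude too weak to do so at c = 0.05.

**Plasticity.** Additive, all-to-all pair-based Hebbian STDP with hard
bounds 0 ≤ W ≤ Wmax; the potentiation branch is gated off at the upper bound
and the depression branch at zero, mirroring how the bound factors attach to
each branch of L(s).  Simultaneous pre/post spikes (lag 0) are credited to
potentiation.  In the simulator the rule is implemented exactly with two
exponential traces per neuron (O(1) work per spike).

**Weight scaling.** Network weights, the motif coordinates, and the rule
amplitudes f± are rescaled by ε = 1/(N p₀) so that the total synaptic input
per neuron is invariant under changes of N or connection probability p₀.
On this scale the mean-weight coordinate p = Σ W_ij /(N² ε) lives in
[0, p₀ Wmax] (default [0, 0.75]), and the standard initial condition is all
synapses equal at half maximum, p(0) = p₀ Wmax/2.

**Rule presets** (`hebbian_rule`): τ₊ = 20 ms, τ₋ = 40 ms, f₊ = 0.1 (unscaled)
by default, with the depression area f₋τ₋ set by a balance mode: exactly
balanced (S = ∫L = 0), balanced tilted by ±δ·ε·f₊τ₊ with δ = 0.1 (the
"balanced potentiation/depression-dominated" regimes), or unbalanced with
the depression (potentiation) area twice the other.  The tilt δ is applied
relative to the potentiation area; this convention, and the pair-circuit
amplitudes used in the examples/tests (f₊ = 0.002–0.008 on the unscaled
pair scale), are choices the source analyses leave open.

## Single-neuron Fokker–Planck numerics

All spectral quantities use the convention y(ω) = ∫ y(t) e^(−2πiωt) dt with
ω in cycles/ms.  One backward "threshold-integration" sweep of the
flux/density pair from Vth down to an absorbing lower bound solves, at every
frequency simultaneously:

- the stationary density and rate, r = 1/(∫p dV + τ_ref);
- the linear response A(ω) (two auxiliary systems: homogeneous and
  modulated-drift, combined via the zero-flux condition at the lower bound;
  reinjection at Vre carries the refractory delay factor e^(−2πiωτ_ref));
- the first-passage-time transform f(ω), whence the renewal power spectrum
  C₀(ω) = r(1−|f|²)/|1−f|², with the refractory period as a pure delay.

Voltage grid: uniform from VL − 5σ to Vth with Vre snapped onto the grid,
~3000 points by default (each step uses the exact exponential integrator for
frozen coefficients, so the grid mainly controls the drift sampling).  The
quantities 0/0-degenerate at ω = 0 are evaluated at a tiny proxy frequency
(10⁻⁵ kHz) and A(0) is forced real.  Self-convergence and oracle tests:
rate vs Monte-Carlo at nine operating points (3 SE), A(0) vs finite-difference
dr/dµ (<1%), C₀(0) vs r·CV² from simulated ISIs, C₀(∞) → r.

Network rates solve r_i = r(µ + τS Σ_j W_ij r_j, σ) by damped fixed-point
iteration (tolerance 10⁻⁶ spikes/ms, 500 iterations, error on divergence —
the rate-instability regime).  For dense per-neuron spectra the solver is
evaluated at 5–7 nodes spanning the µ_eff range and interpolated linearly
(`NeuronStatsTable`); the interpolation error is ~10⁻³ relative over the
narrow µ_eff spreads that weak coupling produces.

## Covariance solves and rule-weighted integrals

Full solve: C(ω) = (I−G)⁻¹ C₀ (I−G)⁻ᴴ with G_ij = A_i(ω)J(ω)W_ij, dense LU
per frequency; a power-iteration estimate of the spectral radius of G(0)
guards the linearization.  Truncation at length-one paths keeps
G C₀ + C₀ Gᴴ + G C₀ Gᴴ off the diagonal (forward, backward, common input).
A third, "homogeneous" flavor replaces every neuron's kernels by the network
average, which collapses the rule-weighted drift to
S_F·W + S_B·Wᵀ + S_C·(WWᵀ) — the same approximation the motif reduction
rests on, and cheap enough for N ~ 10³ at every plasticity step.

Integrals ∫L(s)C_ij(s) ds are evaluated in the frequency domain
(2 Re ∫₀^∞ L̃*(ω)C(ω) dω) on a composite Gauss–Legendre grid with geometric
panels on (0, 1] kHz (9 panels × 10 nodes), dense where L̃ is concentrated
(|ω| ≲ 1/τ₋).  Uniform grids for time-domain transforms default to
dω = 1/512 kHz, |ω| ≤ 1 kHz (lag period 512 ms, resolving the ±250 ms lag
range).  Parseval cross-checks against time-domain quadrature agree to
<0.1%.

## Weight evolution and the reduced motif system

`evolve` Euler-steps dW_ij/dt = W⁰_ij ∫L(s)(r_i r_j + C_ij(s))ds with a
100 s step (50 s halving changes endpoints by <1% while trajectories stay
interior), re-linearizing rates and spectra every step, gating the branches
at the bounds, and clipping after the full increment.  Near the
rate-instability boundary (mean weight close to p₀Wmax at these parameters)
the 100 s explicit step oscillates; trajectories are truncated with an error
flag when the rate solve diverges, and comparisons are restricted to the
pre-bound transient.

The reduced system evolves the 11 coordinates
(p, q^div, q^con, q^ch, q^rec, qX2^rec, qX^rec, qX^div, qX^con, qX^ch,A,
qX^ch,B) with q^op = q^ch − q^rec derived, using four scalars S, S_F, S_B,
S_C and the rate r frozen at the operating point p = p₀Wmax/2 (re-freezing
every step changes trajectories negligibly; a refresh mode exists in
`evolve`'s homogeneous flavor, which recomputes them continuously).
Integration: RK45, rtol 10⁻⁸, atol 10⁻¹²; the reduced system carries no
weight bounds, and trajectories are flagged once p leaves [0, p₀Wmax].

Two consistency subtleties, both verified by independent re-derivation of
the sums and enforced in tests:

- The leading-order closed forms for unbalanced rules integrate
  dq = 2r²S·qX, dqX = r²S·q₀ to q(t) = q(0) + 2qX(0)r²St + q₀(r²St)²; the
  chain variant is driven by qX^ch,A + qX^ch,B with linear coefficient one.
- The unstructured manifold (all motif coordinates zero) is exactly
  invariant for the seven non-reciprocal coordinates; the
  reciprocal-conditioned mixed motif qX^rec carries an O(ε) source term
  ε(1−p₀)p p₀ S_B because its unstructured baseline is itself O(ε).

Fixed points of the unstructured mean-weight dynamics are the roots of
p₀r²S/ε + p(S_F + p₀S_B) + p²S_C; for the depression-tilted balanced rule
one root is negative and the other positive — the separatrix between
potentiation and depression of the mean weight, rising with p₀.

## Network generation

Erdős–Rényi digraphs are independent Bernoulli(p₀) off the diagonal.
Degree-correlated networks draw in/out-degree pairs from a two-piece
truncated power law (C₁d^γ¹ on [0, L₁], C₂d^γ² on [L₁, L₂], continuous at
L₁ and normalized; defaults γ₁ = 0.2, γ₂ = −1, L₁ = N/10, L₂ = N) coupled by
a Gaussian copula with correlation ρ, then sample each edge j→i as an
independent Bernoulli with probability ∝ in_i·out_j scaled so the expected
edge count is N²p₀ (probabilities above one are clipped with a warning;
~1.5% of entries at N = 1000).  Normalization, continuity and a prescribed
mean cannot all hold for the two-piece density with these exponents, so the
mean-degree constraint is enforced through the edge-probability scaling
rather than the degree marginals.  Realized motif frequencies at N = 1000:
q0^div ≈ q0^con ≈ 0.0155 for all ρ, q0^ch ≈ −0.0014, +0.0014, +0.0071 at
ρ = −0.1, +0.1, +0.5.

## What the synthetic conditions do and do not show

The simulator generates the study conditions themselves (no external data):
white-noise-driven EIF networks with internally generated correlations only.
Passing tests show the three levels of description are mutually consistent
in the weak-coupling, balanced-rate regime; they do not speak to
conductance-based synapses, transmission delays, inhibition, rate-unstable
regimes, or non-pair plasticity models, all of which are out of scope.
Linear-response covariances underestimate short-lag synchrony as synapses
strengthen (≈10% at 0.5 µA/cm² per synapse for an isolated pair, worse at
millivolt-scale coupling), so covariance-driven drift comparisons are run at
input-matched network weights where the ansatz is accurate, with tolerances
set by Monte-Carlo error.  The reduced motif system inherits the re-summing
closure (no third- or higher-order weight correlations); on chain-rich
power-law networks the closure overestimates chain drift by factors of ~2 —
a documented qualitative limitation, not corrected for.

## Problem sizes used in tests and the acceptance script

Spike-count correlation protocols: N = 1000 for ≥50 s and N = 100 for
≥100 s of biological time, 100 ms counting windows (50/500 ms give the same
plateau).  Truncated-vs-full comparison: one N = 1000 realization on the
Gauss–Legendre frequency grid; the difference statistic is the mean absolute
rule-weighted-integral difference normalized by the mean magnitude, reported
over ordered pairs lacking the direct forward synapse (where the truncation
actually bites; directly connected entries agree to <1%).  Reduced-vs-full motif comparison: N = 1000,
2000 s transient.  Degree-correlated statistics: 20 seeds at N = 1000.
Trial-averaged drift checks: 8 simulation seeds on N = 100 subnetworks with
a 9-synapse probe set, sized so that 3 standard errors of the Monte-Carlo
mean bound both sampling noise and the linear-response systematic.
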