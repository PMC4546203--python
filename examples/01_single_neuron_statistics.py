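"""Stationary rate, linear response and power spectrum of one EIF neuron.

The threshold-integration solver gives the three single-neuron quantities
the network theory is built from: the stationary rate r at an operating
point (mu, sigma), the transfer function A(omega) from current modulation to
rate modulation, and the baseline spike-train power spectrum C0(omega).
"""

import numpy as np

from motifstdp import EIFParams, linear_response, power_spectrum, \
    stationary_rate

eif = EIFParams()
mu, sigma = 1.0, 9.0

r = stationary_rate(mu, sigma, eif)
om = np.array([0.0, 0.01, 0.1, 1.0])
A = linear_response(mu, sigma, eif, om)
C0 = power_spectrum(mu, sigma, eif, om)

print(f"operating point: mu = {mu} uA/cm^2, sigma = {sigma} mV")
print(f"stationary rate r = {r * 1000:.2f} Hz")
print(f"A(0) = {A[0].real:.5f} spikes/ms per uA/cm^2 "
      "(= dr/dmu, the DC gain)")
for w, a, c in zip(om, A, C0):
    print(f"  omega = {w:5.2f} kHz: |A| = {abs(a):.5f}, C0 = {c:.5f}")
print("|A| decays at high frequency (the neuron low-passes its input); "
      "C0 tends to r, the flat spectrum of the spike point process.")
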