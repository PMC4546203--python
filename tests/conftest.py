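import numpy as np
import pytest

from motifstdp.params import EIFParams, NoiseParams


@pytest.fixture(scope="session")
def eif():
    return EIFParams()


@pytest.fixture(scope="session")
def noise():
    return NoiseParams()


@pytest.fixture(scope="session")
def base_rate(eif, noise):
    """Stationary rate at the bare operating point (mu=1, sigma=9)."""
    from motifstdp.fokker_planck import stationary_rate

    return stationary_rate(noise.mu, noise.sigma, eif)


@pytest.fixture(scope="session")
def frozen_ints(eif, noise):
    """STDP integrals of the balanced depression-dominated rule at the
    frozen operating point of the default network (p0=0.15, wmax=5)."""
    from motifstdp.params import hebbian_rule
    from motifstdp.motifs import stdp_integrals

    rule_hat = hebbian_rule(balance="depression", delta=0.1, epsilon=1.0 / 150)
    return stdp_integrals(rule_hat, p0=0.15, noise=noise, eif=eif), rule_hat


# ---------------------------------------------------------------------------
# Brute-force motif oracles (O(N^3) triple loops); test-suite only
# ---------------------------------------------------------------------------

def brute_motif_frequencies(W0):
    W0 = np.asarray(W0, float)
    N = W0.shape[0]
    p0 = W0.sum() / N**2
    qdiv = qcon = qch = 0.0
    for i in range(N):
        for j in range(N):
            for k in range(N):
                qdiv += W0[i, k] * W0[j, k]
                qcon += W0[i, k] * W0[i, j]
                qch += W0[i, j] * W0[j, k]
    qrec = sum(W0[i, j] * W0[j, i] for i in range(N) for j in range(N))
    return dict(
        p0=p0,
        q0_div=qdiv / N**3 - p0**2,
        q0_con=qcon / N**3 - p0**2,
        q0_ch=qch / N**3 - p0**2,
        q0_rec=qrec / N**2 - p0**2,
    )


def brute_motif_strengths(W, W0, eps):
    W = np.asarray(W, float)
    W0 = np.asarray(W0, float)
    N = W.shape[0]
    p = W.sum() / (N**2 * eps)
    acc = dict(q_div=0.0, q_con=0.0, q_ch=0.0, q_rec=0.0, q_op=0.0,
               qX_div=0.0, qX_con=0.0, qX_chA=0.0, qX_chB=0.0)
    for i in range(N):
        for j in range(N):
            for k in range(N):
                acc["q_div"] += W[i, k] * W[j, k]
                acc["q_con"] += W[i, k] * W[i, j]
                acc["q_ch"] += W[i, j] * W[j, k]
                acc["q_rec"] += (i == k) * W[i, j] * W[j, k]
                acc["q_op"] += (i != k) * W[i, j] * W[j, k]
                acc["qX_div"] += W[i, k] * W0[j, k]
                acc["qX_con"] += W[i, k] * W0[i, j]
                acc["qX_chA"] += W[i, j] * W0[j, k]
                acc["qX_chB"] += W0[i, j] * W[j, k]
    p0 = W0.sum() / N**2
    out = dict(
        p=p,
        q_div=acc["q_div"] / (N**3 * eps**2) - p**2,
        q_con=acc["q_con"] / (N**3 * eps**2) - p**2,
        q_ch=acc["q_ch"] / (N**3 * eps**2) - p**2,
        q_rec=acc["q_rec"] / (N**3 * eps**2),
        q_op=acc["q_op"] / (N**3 * eps**2) - p**2,
        qX_rec=sum(W[i, j] * W0[j, i] for i in range(N) for j in range(N))
        / (N**2 * eps) - p * p0,
        qX_div=acc["qX_div"] / (N**3 * eps) - p * p0,
        qX_con=acc["qX_con"] / (N**3 * eps) - p * p0,
        qX_chA=acc["qX_chA"] / (N**3 * eps) - p * p0,
        qX_chB=acc["qX_chB"] / (N**3 * eps) - p * p0,
        qX2_rec=sum(W[i, j] ** 2 * W0[j, i] for i in range(N)
                    for j in range(N)) / (N**3 * eps**2),
    )
    return out
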