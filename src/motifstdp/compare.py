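"""Comparison reports between simulation, high-dimensional theory and the
reduced motif system."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compare_runs", "envelope_coverage"]


def compare_runs(reference: dict, candidate: dict,
                 tolerances: dict | float = 0.1,
                 times: np.ndarray | None = None) -> pd.DataFrame:
    """Per-quantity relative-error table.

    ``reference`` and ``candidate`` map quantity names to 1-D arrays on a
    shared time axis.  The relative error of each quantity is normalized by
    the reference trajectory's range (its max - min, falling back to its max
    magnitude), which keeps quantities that start near zero comparable.
    """
    rows = []
    for name, ref in reference.items():
        if name not in candidate:
            continue
        ref = np.asarray(ref, dtype=float)
        cand = np.asarray(candidate[name], dtype=float)
        if ref.shape != cand.shape:
            raise ValueError(f"{name}: mismatched shapes {ref.shape} vs "
                             f"{cand.shape}")
        scale = ref.max() - ref.min()
        if scale == 0:
            scale = max(np.abs(ref).max(), 1e-300)
        err = float(np.abs(cand - ref).max() / scale)
        tol = tolerances.get(name, np.inf) if isinstance(tolerances, dict) \
            else float(tolerances)
        rows.append({"quantity": name, "max_rel_err": err,
                     "tolerance": tol, "ok": err <= tol})
    return pd.DataFrame(rows)


def envelope_coverage(theory: np.ndarray, trials: np.ndarray) -> float:
    """Fraction of time points where the theory curve lies inside the
    across-trial min/max envelope; ``trials`` has shape (n_trials, n_t)."""
    lo = trials.min(axis=0)
    hi = trials.max(axis=0)
    inside = (theory >= lo) & (theory <= hi)
    return float(inside.mean())
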