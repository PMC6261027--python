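"""Independent straight-line reference for the multiplicative-update NMF.

Deliberately minimal and separate from the package: same initialization
contract (Uniform(0,1) from a seeded generator) and the textbook
alternating updates written out directly, with no convergence check, so a
trace of any fixed length can be compared against the package's.
"""

import numpy as np

EPS = 1e-12


def reference_nmf_trace(PD, rank, seed, n_iter):
    """Objective trace (length n_iter + 1) of plain multiplicative updates."""
    PD = np.asarray(PD, dtype=float)
    n, m = PD.shape
    rng = np.random.default_rng(seed)
    W = rng.random((n, rank))
    H = rng.random((m, rank))
    trace = [float(((PD - W @ H.T) ** 2).sum())]
    for _ in range(n_iter):
        W = W * (PD @ H) / (W @ (H.T @ H) + EPS)
        H = H * (PD.T @ W) / (H @ (W.T @ W) + EPS)
        trace.append(float(((PD - W @ H.T) ** 2).sum()))
    return np.array(trace), W, H


def reference_nnls_multiplicative(row, H, n_iter=500):
    """Nonnegative projection of one row onto a fixed basis H (M x R)."""
    row = np.asarray(row, dtype=float)
    h = np.ones(H.shape[1])
    G = H.T @ H
    num = row @ H
    for _ in range(n_iter):
        h = h * num / (h @ G + EPS)
    return h
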