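"""Independent brute-force oracles shared by the test suite.

These deliberately re-derive quantities by exhaustive enumeration or
first-principles formulas, independent of the package's implementations.
"""

import numpy as np

from covnet.community import signed_modularity_matrix


def brute_force_clustering(w: np.ndarray) -> np.ndarray:
    """Signed clustering via exhaustive ordered (j, k) triple enumeration."""
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    m = np.abs(w).max()
    if m > 0:
        w = w / m
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            for k in range(n):
                if j != i and k != i and k != j:
                    num += w[i, j] * w[j, k] * w[k, i]
                    den += abs(w[i, j] * w[k, i])
        out[i] = num / den if den > 0 else 0.0
    return out


def set_partitions(n):
    """All set partitions of n elements (restricted growth strings)."""
    def rec(prefix, maxl):
        if len(prefix) == n:
            yield list(prefix)
            return
        for l in range(maxl + 2):
            yield from rec(prefix + [l], max(maxl, l))
    yield from rec([], -1)


def exhaustive_optimum(w: np.ndarray, gamma: float = 1.0):
    """Globally optimal signed-modularity score by exhaustive search."""
    B = signed_modularity_matrix(w, gamma)
    best, best_labels = -np.inf, None
    for labels in set_partitions(w.shape[0]):
        la = np.array(labels)
        q = B[la[:, None] == la[None, :]].sum()
        if q > best:
            best, best_labels = q, la
    return best, best_labels


def bh_stepup_oracle(p, q):
    """Hand-coded Benjamini-Hochberg step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    below = p[order] <= q * np.arange(1, m + 1) / m
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    return rejected, adjusted


def random_signed_net(n, rng, sparsity=0.3):
    w = rng.uniform(-1, 1, (n, n))
    w[rng.random((n, n)) < sparsity] = 0.0
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w
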