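"""Independent brute-force oracles used to check the fast implementations.

Deliberately naive: the tabular relationship recursion, literal O(m^2)
epistatic pair sums, and a direct agglomerative clustering — none of them
share code with the package paths they verify.
"""

from __future__ import annotations

import numpy as np


def tabular_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Classical tabular numerator relationship matrix.

    A_ij = 0.5 (A_j,s(i) + A_j,d(i)) for j < i and A_ii = 1 + 0.5 A_s(i),d(i),
    with any term involving an unknown parent (-1) equal to zero.  Assumes
    parents precede offspring.
    """
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def pairwise_epistatic(Z: np.ndarray, W: np.ndarray, effect: str) -> np.ndarray:
    """Literal triangular pair sum over loci k < k' of the Table-style
    outer products (before mean-diagonal normalization)."""
    first, second = {
        "aa": (Z, Z),
        "dd": (W, W),
        "ad": (Z, W),
        "da": (W, Z),
    }[effect]
    n, m = Z.shape
    K = np.zeros((n, n))
    for k in range(m - 1):
        for kp in range(k + 1, m):
            v = first[:, k] * second[:, kp]
            K += np.outer(v, v)
    return K


def agglomerate(D: np.ndarray, linkage: str = "average"):
    """Naive agglomerative clustering; returns the merge list
    [(members_a, members_b, height), ...] in merge order."""
    clusters = [[i] for i in range(D.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dists = [D[i, j] for i in clusters[a] for j in clusters[b]]
                if linkage == "average":
                    d = float(np.mean(dists))
                elif linkage == "complete":
                    d = float(np.max(dists))
                else:
                    d = float(np.min(dists))
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((sorted(clusters[a]), sorted(clusters[b]), d))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [
            clusters[a] + clusters[b]
        ]
    return merges
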