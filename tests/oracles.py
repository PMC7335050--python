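"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the package code paths:
Horn's quaternion eigenvalue method for best-fit RMSD, a naive
recompute-from-scratch average-linkage clusterer, and the hypergeometric
tail for set enrichment.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def quaternion_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Best-fit RMSD via the largest eigenvalue of Horn's 4x4 key matrix."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    S = Xc.T @ Yc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = ((Xc**2).sum() + (Yc**2).sum() - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def naive_average_linkage(D: np.ndarray, epsilon: float) -> np.ndarray:
    """O(n^3)-ish reference: inter-cluster distances recomputed from the
    original matrix as the mean over all cross-member pairs each iteration.

    Clusters are keyed by their lowest member; distance ties resolve to the
    lexicographically lowest key pair (strict ``<`` over sorted keys).
    Returns labels with cluster 0 the most populated (ties: lowest member).
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ii, a in enumerate(keys):
            for b in keys[ii + 1 :]:
                d = float(D[np.ix_(clusters[a], clusters[b])].mean())
                if best is None or d < best[0]:
                    best = (d, a, b)
        if best[0] > epsilon:
            break
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    order = sorted(clusters, key=lambda k: (-len(clusters[k]), min(clusters[k])))
    labels = np.empty(n, dtype=int)
    for lab, key in enumerate(order):
        labels[clusters[key]] = lab
    return labels


def enrichment_tail_exact(n_assigned: int, n_in_groove: int, n_perturbed: int,
                          observed: int) -> float:
    """P(X >= observed) for X ~ Hypergeom: exact null of the permutation test."""
    return float(hypergeom.sf(observed - 1, n_assigned, n_in_groove, n_perturbed))
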