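"""Minimal partitioning-around-medoids (PAM) on a precomputed distance matrix.

Only what the unsupervised reference search needs: BUILD-style greedy
initialisation followed by alternating assignment / medoid update.
Sample counts here are small (tens to a few hundred), so the O(n^2)
updates are immaterial.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pam"]


def pam(
    dist: np.ndarray,
    n_clusters: int,
    rng: np.random.Generator | None = None,
    max_iter: int = 100,
) -> np.ndarray:
    """Cluster points given an n x n distance matrix; returns labels 0..k-1.

    Initialisation is deterministic (greedy BUILD): the first medoid
    minimises total distance, each further medoid maximises the drop in
    total point-to-nearest-medoid distance.  ``rng`` only breaks exact
    ties, so results are reproducible for a fixed generator state.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[1] != n:
        raise ValueError("dist must be a square distance matrix")
    if not 2 <= n_clusters <= n:
        raise ValueError("n_clusters must be between 2 and the sample count")

    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < n_clusters:
        cur = dist[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        if rng is not None:
            ties = np.flatnonzero(gains == gains[best])
            best = int(rng.choice(ties))
        medoids.append(best)

    medoids = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(n_clusters):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return np.argmin(dist[:, medoids], axis=1)
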