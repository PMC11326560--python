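"""Vectorized inner loop for sequential-removal MSS evaluation.

Evaluating one removal step means scoring B candidate subsets, each
under R random bipartitions.  Doing this with the object-level
primitives is O(B * R) Python iterations; here the R amalgamations of a
candidate collapse into a single matrix product

    col_A = M @ Z.T          (n x R)
    col_B = kept_total - col_A

where Z is an R x p 0/1 block-membership matrix with the candidate's
removed columns zeroed.  Group-mean log-ratios then follow from one
indicator matmul.  The result is bit-identical across runs because every
candidate draws its partitions from a dedicated ``SeedSequence`` keyed
by (master seed, context, step k, candidate b) — changing B or R never
reshuffles the draws of other candidates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["candidate_partition_bits", "step_mss", "logratio_group_means"]


def _rng_for(master_seed: int, context: int, k: int, b: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(master_seed), context, k, b]))
    )


def candidate_partition_bits(
    rng: np.random.Generator, R: int, p: int, removed: np.ndarray
) -> np.ndarray:
    """R x p 0/1 matrix of block-A membership over the kept taxa.

    Removed columns are zero; every row has at least one kept taxon in
    each block (rows violating this are redrawn, matching the
    fair-coin-with-rejection scheme of ``random_bipartition``).
    """
    removed = np.asarray(removed, dtype=int)
    q = p - removed.size
    if q < 2:
        raise ValueError("need at least 2 kept taxa to bipartition")
    bits = rng.integers(0, 2, size=(R, p), dtype=np.int8)
    if removed.size:
        bits[:, removed] = 0
    kept_sum = bits.sum(axis=1)
    bad = np.flatnonzero((kept_sum == 0) | (kept_sum == q))
    while bad.size:
        redraw = rng.integers(0, 2, size=(bad.size, p), dtype=np.int8)
        if removed.size:
            redraw[:, removed] = 0
        bits[bad] = redraw
        kept_sum = bits[bad].sum(axis=1)
        bad = bad[(kept_sum == 0) | (kept_sum == q)]
    return bits


def logratio_group_means(
    col_a: np.ndarray,
    col_b: np.ndarray,
    indicator: np.ndarray,
    group_sizes: np.ndarray,
    zero_replacement: float,
) -> np.ndarray:
    """G x R group means of log(col_a) - log(col_b) with zero handling."""
    col_a = np.where(col_a == 0, zero_replacement, col_a)
    col_b = np.where(col_b == 0, zero_replacement, col_b)
    lr = np.log(col_a) - np.log(col_b)
    return (indicator @ lr) / group_sizes[:, None]


def step_mss(
    M: np.ndarray,
    indicator: np.ndarray,
    group_sizes: np.ndarray,
    candidates: list[np.ndarray],
    R: int,
    master_seed: int,
    context: int,
    k: int,
    zero_replacement: float = 0.5,
) -> np.ndarray:
    """MSS for every candidate removal at one step.

    Parameters
    ----------
    M : n x p abundance matrix restricted to the currently kept taxa.
    indicator : G x n group indicator matrix.
    group_sizes : per-group sample counts.
    candidates : per candidate, the column indices (into ``M``) removed.
    R : number of random amalgamations per candidate.
    master_seed, context, k : ingredients of the per-candidate seed
        stream (``context`` distinguishes the observed-data search from
        each label permutation of the null builder).

    Returns the length-B array of Q values.
    """
    M = np.asarray(M, dtype=float)
    n, p = M.shape
    row_tot = M.sum(axis=1)
    G = indicator.shape[0]
    iu, ju = np.triu_indices(G, k=1)
    out = np.empty(len(candidates))
    for b, removed in enumerate(candidates):
        removed = np.asarray(removed, dtype=int)
        rng = _rng_for(master_seed, context, k, b)
        bits = candidate_partition_bits(rng, R, p, removed)
        col_a = M @ bits.T.astype(float)
        kept_tot = row_tot - (M[:, removed].sum(axis=1) if removed.size else 0.0)
        col_b = np.maximum(kept_tot[:, None] - col_a, 0.0)
        X = logratio_group_means(col_a, col_b, indicator, group_sizes, zero_replacement)
        diff = X[iu] - X[ju]
        out[b] = float((diff * diff).sum()) / R
    return out
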