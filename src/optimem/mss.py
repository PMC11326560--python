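"""The mean sum of squared log-ratio differences (MSS) statistic.

For a candidate taxon subset, the subset matrix is repeatedly collapsed
into two columns by random amalgamation; each collapse yields one
group-mean log-ratio per group.  The MSS statistic Q is the mean over
amalgamations of the sum over unordered group pairs of squared
differences in these log-ratios:

    Q = (1/R) * sum_{i<j} sum_r (x_i[r] - x_j[r])**2

where ``x_g[r]`` is the group-g mean of ``log(block A) - log(block B)``
under the r-th random bipartition.  Q is zero in expectation exactly
when the subset contains no taxa whose relative abundances differ
across groups, and it is invariant to per-sample rescaling (sequencing
depth) because the scaling cancels in the ratio.

Two equivalent computational routes are provided: a Gram-matrix
formulation (inner products of the per-group log-ratio vectors) and a
direct pairwise-difference sum.  The direct route is the production
default; the Gram route is retained and cross-checked in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_ZERO_REPLACEMENT,
    Bipartition,
    GroupLabels,
    TaxonomicProfile,
    TaxonSubset,
    amalgamate_pair,
    closure,
    mean_logratio,
    select_subset,
)

__all__ = [
    "LogRatioBlock",
    "MssValue",
    "gram_matrix",
    "mss_from_gram",
    "mss_from_logratios",
    "mss",
    "naive_w",
    "group_logratio_means",
]


@dataclass
class LogRatioBlock:
    """G x R matrix of group-mean log-ratios; row g holds the R draws."""

    X: np.ndarray
    k: int = 0
    b: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a G x R matrix")
        if self.X.shape[0] < 2:
            raise ValueError("need at least two groups")
        if self.X.shape[1] < 1:
            raise ValueError("need at least one amalgamation")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("log-ratio block contains non-finite entries")


@dataclass
class MssValue:
    """An MSS statistic with its provenance (removal step, candidate)."""

    Q: float
    k: int = 0
    b: int = 0
    R: int = 1

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("Q must be non-negative")


def gram_matrix(block: LogRatioBlock | np.ndarray) -> np.ndarray:
    """G x G matrix of inner products of the per-group log-ratio vectors."""
    X = block.X if isinstance(block, LogRatioBlock) else np.asarray(block, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite log-ratio input")
    return X @ X.T


def mss_from_gram(H: np.ndarray, R: int, k: int = 0, b: int = 0) -> MssValue:
    """MSS from the Gram matrix: Q = sum_{i<j} ||x_i - x_j||^2 / R.

    Computed via the squared-distance decomposition
    ``D = (diag(H) 1' + 1 diag(H)' - 2 H) / (2R)`` summed over all
    entries, which double-counts each unordered pair and so recovers
    the pairwise sum exactly.
    """
    if R < 1:
        raise ValueError("R must be a positive integer")
    H = np.asarray(H, dtype=float)
    d = np.diag(H)
    D = (d[:, None] + d[None, :] - 2.0 * H) / (2.0 * R)
    return MssValue(Q=float(max(D.sum(), 0.0)), k=k, b=b, R=R)


def mss_from_logratios(block: LogRatioBlock) -> MssValue:
    """MSS by the direct pairwise-difference route (production default)."""
    X = block.X
    g, r = X.shape
    q = 0.0
    for i in range(g):
        for j in range(i + 1, g):
            diff = X[i] - X[j]
            q += float(diff @ diff)
    return MssValue(Q=q / r, k=block.k, b=block.b, R=r)


def group_logratio_means(
    m2: np.ndarray,
    groups: GroupLabels,
    zero_replacement: float = DEFAULT_ZERO_REPLACEMENT,
) -> np.ndarray:
    """Per-group mean log-ratio of an n x 2 amalgamated matrix."""
    return np.array(
        [
            mean_logratio(m2[groups.codes == g], zero_replacement)
            for g in range(groups.n_groups)
        ]
    )


def mss(
    profile: TaxonomicProfile,
    groups: GroupLabels,
    subset: TaxonSubset,
    partitions: list[Bipartition],
    zero_replacement: float = DEFAULT_ZERO_REPLACEMENT,
    method: str = "direct",
) -> MssValue:
    """MSS of one candidate subset under an explicit list of bipartitions.

    Deterministic given its inputs: draw the partitions separately (see
    :func:`optimem.core.random_bipartition`).  Partitions index into the
    columns of the *selected* submatrix.
    """
    if profile.n_samples != groups.codes.size:
        raise ValueError("labels do not align with profile samples")
    sub = select_subset(profile, subset)
    X = np.empty((groups.n_groups, len(partitions)))
    for r, part in enumerate(partitions):
        m2 = amalgamate_pair(sub.abundance, part)
        X[:, r] = group_logratio_means(m2, groups, zero_replacement)
    block = LogRatioBlock(X=X, k=subset.k, b=0)
    if method == "gram":
        return mss_from_gram(gram_matrix(block), R=X.shape[1], k=subset.k)
    if method == "direct":
        return mss_from_logratios(block)
    raise ValueError(f"unknown method {method!r}")


def naive_w(
    profile: TaxonomicProfile, groups: GroupLabels, subset: TaxonSubset
) -> float:
    """Squared mean-composition differences between all group pairs.

    The naive alternative to MSS: close each group's mean abundance
    vector over the subset and sum squared component-wise differences
    over unordered group pairs.  Exposed for comparison only — the
    estimate of a mean composition is unstable for sparse
    high-dimensional data, which is what motivates the amalgamation
    statistic.
    """
    sub = select_subset(profile, subset)
    means = []
    for g in range(groups.n_groups):
        m = sub.abundance[groups.codes == g].mean(axis=0)
        if m.sum() <= 0:
            raise ValueError(f"group {groups.group_names[g]!r} has all-zero mean")
        means.append(closure(m))
    w = 0.0
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            diff = means[i] - means[j]
            w += float(diff @ diff)
    return w
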