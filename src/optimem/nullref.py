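"""Permutation null distribution of first-step MSS and stopping rules.

The sequential removal needs a data-driven notion of "no group
difference left".  Following a gap-statistic-style construction, group
labels are repeatedly shuffled and the first-step MSS values Q(1, b)
recomputed under each shuffle; pooling them yields the null
distribution MSS_0.  The search stops once the observed best MSS drops
below the empirical mean or a lower percentile of MSS_0, and the
position of the *first* observed MSS relative to the null upper limit
classifies the overall outcome:

* first-step MSS already at or below the null upper limit — nothing
  distinguishes the groups beyond chance; all taxa are reported non-DA;
* the search hits the 10 %-of-taxa floor with MSS still above the null —
  everything looks differentially abundant (or group compositions are
  entirely distinct);
* otherwise the surviving taxa form the reference set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import GroupLabels, TaxonomicProfile

__all__ = [
    "NullDistribution",
    "build_null",
    "stopping_threshold",
    "classify_outcome",
]

#: Seed-stream contexts: the observed-data search uses context 0; the
#: i-th label permutation of the null builder uses NULL_CONTEXT + i.
NULL_CONTEXT = 1_000_000


@dataclass
class NullDistribution:
    """Pooled first-step MSS values under shuffled group labels."""

    samples: np.ndarray
    alpha: float = 0.05
    n_perm: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("empty null distribution")
        if np.any(self.samples < 0):
            raise ValueError("MSS values must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    def percentile(self, q: float) -> float:
        """Empirical lower-tail q-quantile of the null samples."""
        if not 0 < q < 1:
            raise ValueError("quantile level must be in (0, 1)")
        return float(np.quantile(self.samples, q))

    @property
    def lower_limit(self) -> float:
        """Lower limit of MSS_0 at the distribution's alpha."""
        return self.percentile(self.alpha)

    @property
    def upper_limit(self) -> float:
        """Upper limit of MSS_0 at the distribution's alpha."""
        return self.percentile(1.0 - self.alpha)


def build_null(
    profile: TaxonomicProfile,
    groups: GroupLabels,
    B: int,
    R: int,
    n_perm: int = 20,
    seed: int = 0,
    eta: float | None = None,
    alpha: float = 0.05,
    zero_replacement: float = 0.5,
) -> NullDistribution:
    """Pool first-step MSS values over ``n_perm`` label shuffles.

    For each shuffle, Q(1, b) is evaluated for ``B`` candidate removals
    (single-taxon removals when ``eta`` is None or <= 1/p, otherwise
    random eta-fraction removals) with fresh partitions per candidate.
    All resulting values are pooled, giving ``n_perm * B`` null draws.
    """
    from ._engine import step_mss

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if B < 1 or R < 1:
        raise ValueError("B and R must be >= 1")
    M = profile.abundance
    n, p = M.shape
    single = eta is None or eta <= 1.0 / p
    perm_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 888_777_666]))
    sizes = groups.group_sizes.astype(float)

    pooled = []
    for i in range(n_perm):
        codes = perm_rng.permutation(groups.codes)
        ind = np.zeros((groups.n_groups, n))
        ind[codes, np.arange(n)] = 1.0
        if single:
            cands = [np.array([j]) for j in range(min(B, p))]
        else:
            m = max(1, p - int(np.floor((1.0 - eta) * p)))
            cands = [perm_rng.choice(p, size=m, replace=False) for _ in range(B)]
        q = step_mss(
            M, ind, sizes, cands, R,
            master_seed=seed, context=NULL_CONTEXT + i, k=1,
            zero_replacement=zero_replacement,
        )
        pooled.append(q)
    return NullDistribution(
        samples=np.concatenate(pooled), alpha=alpha, n_perm=n_perm
    )


def stopping_threshold(
    null: NullDistribution, mode: str = "percentile", alpha: float | None = None
) -> float:
    """Stopping criterion: empirical mean or lower alpha-percentile of MSS_0."""
    if mode == "mean":
        return null.mean
    if mode == "percentile":
        a = null.alpha if alpha is None else alpha
        return null.percentile(a)
    raise ValueError("mode must be 'mean' or 'percentile'")


def classify_outcome(
    first_q: float,
    null: NullDistribution,
    floor_reached: bool = False,
    trace_q: np.ndarray | None = None,
) -> str:
    """Classify a finished search: ref_found, no_da_taxa, or all_da_taxa.

    ``no_da_taxa``: the very first best MSS is not above the null upper
    limit, so the data are indistinguishable from label-shuffled data
    and every taxon is reported non-DA.  (Values *below* the lower null
    limit are likewise no evidence of differential abundance.)

    ``all_da_taxa``: the search exhausted its taxon budget (the 10 %
    floor) without the MSS dropping to the stopping criterion; when the
    recorded MSS trace is not entirely above the null upper limit this
    is reported with a warning since the pattern is then ambiguous.
    """
    upper = null.upper_limit
    if floor_reached:
        if trace_q is not None and not np.all(np.asarray(trace_q) > upper):
            warnings.warn(
                "taxon floor reached but some MSS values fell below the null "
                "upper limit; classifying as all_da_taxa is tentative",
                stacklevel=2,
            )
        return "all_da_taxa"
    if first_q <= upper:
        return "no_da_taxa"
    return "ref_found"
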