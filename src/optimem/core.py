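"""Compositional primitives: closure, selection, amalgamation, log-ratios.

Microbiome count tables only carry relative information: multiplying a
sample row by any positive constant describes the same composition.  All
machinery built on top of this module therefore works with operations
that are either invariant to such rescaling (ratios, log-ratios) or make
the constraint explicit (the closure operator, which maps counts to
proportions on the simplex).

The module also hosts the exhaustive "minimal assumption" diagnostic:
absolute group differences are recoverable from relative data only when
the largest subset of differentially abundant (DA) taxa whose
within-subset proportions agree across groups is strictly smaller than
the set of non-DA taxa.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaxonomicProfile",
    "GroupLabels",
    "TaxonSubset",
    "Bipartition",
    "closure",
    "select_subset",
    "amalgamate_pair",
    "random_bipartition",
    "mean_logratio",
    "max_subcompositionally_equivalent_set",
]

#: Pseudocount substituted for amalgamated block sums that are exactly
#: zero before taking logs (half of the smallest possible positive count).
DEFAULT_ZERO_REPLACEMENT = 0.5


class InvalidCompositionError(ValueError):
    """Raised for vectors that cannot represent a composition."""


class InvalidPartitionError(ValueError):
    """Raised for bipartitions that do not split the taxon set properly."""


@dataclass
class TaxonomicProfile:
    """A samples x taxa abundance matrix with identifiers.

    Rows are samples, columns are taxa.  Entries are non-negative counts
    (or rescaled counts; all downstream statistics are invariant to
    per-sample scaling).
    """

    abundance: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if self.abundance.ndim != 2:
            raise ValueError("abundance must be a 2-D samples x taxa matrix")
        n, p = self.abundance.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.taxon_ids) != p:
            raise ValueError(f"{len(self.taxon_ids)} taxon ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != p:
            raise ValueError("duplicate taxon identifiers")
        if not np.all(np.isfinite(self.abundance)):
            raise ValueError("abundance contains non-finite entries")
        if np.any(self.abundance < 0):
            i, j = np.argwhere(self.abundance < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.abundance.shape[1]

    def validate_for_analysis(self, min_samples: int = 4, min_taxa: int = 5) -> None:
        """Check the invariants needed before running the reference search."""
        n, p = self.abundance.shape
        if n < min_samples:
            raise ValueError(f"need at least {min_samples} samples, got {n}")
        if p < min_taxa:
            raise ValueError(f"need at least {min_taxa} taxa, got {p}")
        row_tot = self.abundance.sum(axis=1)
        if np.any(row_tot <= 0):
            bad = [self.sample_ids[i] for i in np.flatnonzero(row_tot <= 0)]
            raise ValueError(f"samples with zero total abundance: {bad}")
        col_tot = self.abundance.sum(axis=0)
        if np.any(col_tot <= 0):
            bad = [self.taxon_ids[j] for j in np.flatnonzero(col_tot <= 0)]
            raise ValueError(f"taxa never observed: {bad}")


@dataclass
class GroupLabels:
    """Per-sample group assignment over ``G >= 2`` groups.

    ``codes`` are integers in ``0..G-1`` aligned positionally with the
    rows of a :class:`TaxonomicProfile`; ``group_names`` maps codes back
    to the original labels.  ``source`` records whether membership was
    observed or derived by clustering.
    """

    codes: np.ndarray
    group_names: list[str]
    source: str = "observed"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 1:
            raise ValueError("codes must be 1-D")
        if self.source not in ("observed", "clustered"):
            raise ValueError("source must be 'observed' or 'clustered'")
        g = len(self.group_names)
        if g < 2:
            raise ValueError("need at least two groups")
        if self.codes.min() < 0 or self.codes.max() >= g:
            raise ValueError("codes out of range for group_names")
        counts = np.bincount(self.codes, minlength=g)
        if np.any(counts < 2):
            small = [self.group_names[i] for i in np.flatnonzero(counts < 2)]
            raise ValueError(f"groups with fewer than 2 samples: {small}")

    @classmethod
    def from_values(cls, values, source: str = "observed") -> "GroupLabels":
        """Build labels from an arbitrary sequence of group values."""
        values = list(values)
        names = sorted({str(v) for v in values})
        lookup = {v: i for i, v in enumerate(names)}
        codes = np.array([lookup[str(v)] for v in values], dtype=int)
        return cls(codes=codes, group_names=names, source=source)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.n_groups)

    def indicator(self) -> np.ndarray:
        """G x n one-hot matrix (rows sum to the group sizes)."""
        g = self.n_groups
        ind = np.zeros((g, self.codes.size))
        ind[self.codes, np.arange(self.codes.size)] = 1.0
        return ind


@dataclass
class TaxonSubset:
    """An ordered selection of taxon columns at removal depth ``k``."""

    keep: np.ndarray
    k: int = 0

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=int)
        if self.keep.ndim != 1:
            raise ValueError("keep must be a 1-D index list")
        if len(set(self.keep.tolist())) != self.keep.size:
            raise IndexError("duplicate indices in subset")
        if self.k < 0:
            raise ValueError("removal depth k must be >= 0")

    @classmethod
    def full(cls, p: int) -> "TaxonSubset":
        return cls(keep=np.arange(p), k=0)

    def __len__(self) -> int:
        return self.keep.size


@dataclass
class Bipartition:
    """A two-block partition of a taxon index set; both blocks non-empty."""

    block_a: np.ndarray
    block_b: np.ndarray

    def __post_init__(self) -> None:
        self.block_a = np.asarray(self.block_a, dtype=int)
        self.block_b = np.asarray(self.block_b, dtype=int)
        if self.block_a.size == 0 or self.block_b.size == 0:
            raise InvalidPartitionError("both blocks must be non-empty")
        a, b = set(self.block_a.tolist()), set(self.block_b.tolist())
        if a & b:
            raise InvalidPartitionError("blocks overlap")


def closure(w) -> np.ndarray:
    """Scale a non-negative vector to unit sum (counts -> proportions).

    Zeros propagate as zeros; the vector must have a strictly positive
    total.  Scale invariant: ``closure(a * w) == closure(w)`` for a > 0.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise InvalidCompositionError("composition parts must be non-negative")
    total = w.sum()
    if total <= 0:
        raise InvalidCompositionError("composition must have positive total")
    return w / total


def select_subset(profile: TaxonomicProfile, subset: TaxonSubset) -> TaxonomicProfile:
    """Select the ``subset.keep`` taxon columns, order preserved."""
    p = profile.n_taxa
    if subset.keep.size and (subset.keep.min() < 0 or subset.keep.max() >= p):
        raise IndexError("subset index out of range")
    return TaxonomicProfile(
        abundance=profile.abundance[:, subset.keep],
        sample_ids=profile.sample_ids,
        taxon_ids=[profile.taxon_ids[j] for j in subset.keep],
    )


def amalgamate_pair(abundance, part: Bipartition) -> np.ndarray:
    """Sum taxa into two blocks, returning an ``n x 2`` matrix.

    Accepts a raw matrix or a :class:`TaxonomicProfile`.  The partition
    must cover exactly the columns of the input.  Per-sample totals are
    conserved.
    """
    if isinstance(abundance, TaxonomicProfile):
        abundance = abundance.abundance
    m = np.asarray(abundance, dtype=float)
    covered = np.sort(np.concatenate([part.block_a, part.block_b]))
    if covered.size != m.shape[1] or not np.array_equal(covered, np.arange(m.shape[1])):
        raise InvalidPartitionError("partition must cover exactly the input taxa")
    return np.column_stack(
        [m[:, part.block_a].sum(axis=1), m[:, part.block_b].sum(axis=1)]
    )


def random_bipartition(taxa, rng: np.random.Generator) -> Bipartition:
    """Draw a random bipartition by independent fair-coin assignment.

    Each taxon lands in block A with probability 1/2; draws with an
    empty block are rejected and redrawn, so both blocks are always
    non-empty.
    """
    taxa = np.asarray(taxa, dtype=int)
    if taxa.size < 2:
        raise InvalidPartitionError("need at least 2 taxa to bipartition")
    while True:
        mask = rng.integers(0, 2, size=taxa.size).astype(bool)
        if mask.any() and not mask.all():
            return Bipartition(block_a=taxa[mask], block_b=taxa[~mask])


def mean_logratio(
    m2: np.ndarray, zero_replacement: float = DEFAULT_ZERO_REPLACEMENT
) -> float:
    """Mean over samples of ``log(col 1) - log(col 2)`` of an n x 2 matrix.

    Amalgamated block sums that are exactly zero are replaced by
    ``zero_replacement`` (default 0.5, a half-count pseudocount on the
    amalgamated scale) before logging.  Negative entries are a domain
    error.
    """
    m2 = np.asarray(m2, dtype=float)
    if m2.ndim != 2 or m2.shape[1] != 2:
        raise ValueError("expected an n x 2 amalgamated matrix")
    if np.any(m2 < 0):
        i = int(np.argwhere(m2 < 0)[0][0])
        raise ValueError(f"negative amalgamated abundance in sample row {i}")
    m2 = np.where(m2 == 0, zero_replacement, m2)
    if np.any(m2 <= 0):
        i = int(np.argwhere(m2 <= 0)[0][0])
        raise ValueError(f"non-positive entry after zero handling in sample row {i}")
    return float(np.mean(np.log(m2[:, 0]) - np.log(m2[:, 1])))


def _closures_equal(mu_block: np.ndarray, tol: float) -> bool:
    """True when the closed versions of all rows of ``mu_block`` agree."""
    closed = mu_block / mu_block.sum(axis=1, keepdims=True)
    return bool(np.all(np.abs(closed - closed[0]) <= tol * np.maximum(np.abs(closed[0]), 1e-300)))


def max_subcompositionally_equivalent_set(
    mu_list,
    tol: float = 1e-8,
    max_taxa: int = 20,
) -> tuple[list[int], int, bool]:
    """Exhaustive minimal-assumption diagnostic on true group means.

    Given one mean-abundance vector per group (on the absolute scale),
    returns ``(non_da, s_max, assumption_holds)`` where ``non_da`` lists
    the taxa whose means agree across all groups, ``s_max`` is the size
    of the largest subset of DA taxa whose within-subset proportions are
    identical across groups, and ``assumption_holds`` is
    ``s_max < len(non_da)``.

    Intended as a small-p teaching/diagnostic utility: the subset search
    is exhaustive and refuses more than ``max_taxa`` taxa.
    """
    mu = np.asarray(mu_list, dtype=float)
    if mu.ndim != 2:
        raise ValueError("mu_list must be G vectors of equal length")
    g, p = mu.shape
    if g < 2:
        raise ValueError("need at least two groups")
    if np.any(mu <= 0):
        raise ValueError("true mean abundances must be strictly positive")
    if p > max_taxa:
        raise ValueError(
            f"exhaustive subset search refuses p={p} > {max_taxa} taxa; "
            "this diagnostic is combinatorial — restrict to a small taxon set"
        )

    rel = np.abs(mu - mu[0]) <= tol * np.abs(mu[0])
    non_da = [j for j in range(p) if rel[:, j].all()]
    da = [j for j in range(p) if j not in non_da]

    s_max = 0
    for size in range(len(da), 0, -1):
        found = False
        for combo in itertools.combinations(da, size):
            if _closures_equal(mu[:, list(combo)], tol):
                found = True
                break
        if found:
            s_max = size
            break
    return non_da, s_max, s_max < len(non_da)
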