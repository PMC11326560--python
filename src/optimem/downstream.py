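"""Reference-based ratio normalization and rank-test DA analysis.

Once a non-DA reference set is in hand, dividing every taxon's count by
the per-sample *sum* of the reference taxa yields ratios that are free
of the unit-sum constraint and of sequencing depth: the reference sum
plays the role the geometric mean plays in the CLR transform, but is
built only from taxa believed equal across groups, so true group
differences are preserved rather than smeared across all taxa.

Differential abundance is then assessed per taxon by the Wilcoxon
rank-sum test (two groups) or the Kruskal–Wallis test (three or more),
with Benjamini–Hochberg control of the false discovery rate.  Rank
tests are used because ratios — unlike log-ratios — are far from
normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GroupLabels, TaxonomicProfile
from .search import ReferenceSet

__all__ = ["RatioProfile", "DAResult", "ratio_transform", "da_test", "bh_adjust"]


@dataclass
class RatioProfile:
    """Taxon abundance divided by the per-sample reference-set sum."""

    ratios: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    reference_taxa: list[str]

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)


@dataclass
class DAResult:
    """Per-taxon rank-test results with BH-adjusted q-values."""

    table: pd.DataFrame
    test: str
    fdr_target: float

    @property
    def calls(self) -> np.ndarray:
        return self.table["da_call"].to_numpy()

    @property
    def n_called(self) -> int:
        return int(self.table["da_call"].sum())


def ratio_transform(
    profile: TaxonomicProfile,
    reference: ReferenceSet | list[str],
    zero_replacement: float = 0.5,
) -> RatioProfile:
    """Divide every taxon by the per-sample sum over the reference taxa.

    ``reference`` may be a :class:`ReferenceSet` or a plain list of
    taxon identifiers.  A reference sum of exactly zero in some sample
    is replaced by ``zero_replacement`` (and the affected samples are
    reported in the error message if the policy is disabled with
    ``zero_replacement=0``).  Zero numerators are kept: a ratio of zero
    is informative for rank tests.
    """
    ref_taxa = reference.taxa if isinstance(reference, ReferenceSet) else list(reference)
    if not ref_taxa:
        raise ValueError("reference set is empty")
    lookup = {t: j for j, t in enumerate(profile.taxon_ids)}
    missing = [t for t in ref_taxa if t not in lookup]
    if missing:
        raise ValueError(f"reference taxa not in profile: {missing}")
    idx = np.array([lookup[t] for t in ref_taxa])
    denom = profile.abundance[:, idx].sum(axis=1)
    zero_rows = np.flatnonzero(denom == 0)
    if zero_rows.size:
        if zero_replacement <= 0:
            bad = [profile.sample_ids[i] for i in zero_rows]
            raise ValueError(f"zero reference sum in samples: {bad}")
        denom = np.where(denom == 0, zero_replacement, denom)
    return RatioProfile(
        ratios=profile.abundance / denom[:, None],
        taxon_ids=list(profile.taxon_ids),
        sample_ids=list(profile.sample_ids),
        reference_taxa=list(ref_taxa),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, length preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_test(
    values: np.ndarray, codes: np.ndarray, n_groups: int, exact: bool
) -> tuple[float, float]:
    samples = [values[codes == g] for g in range(n_groups)]
    if n_groups == 2:
        method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def da_test(
    rp: RatioProfile,
    groups: GroupLabels,
    fdr_target: float = 0.05,
    include_reference: bool = True,
    exact: bool | None = None,
) -> DAResult:
    """Per-taxon two-sided rank test on reference ratios, BH-adjusted.

    Two groups use the Wilcoxon rank-sum (Mann–Whitney) test — exact
    when every group has fewer than 20 samples unless overridden —
    and three or more groups use Kruskal–Wallis.  Reference taxa are
    tested by default (the search can err; their ratios remain
    informative); set ``include_reference=False`` to drop them.
    Constant-ratio taxa get p = 1 and are flagged.
    """
    if len(groups.codes) != rp.ratios.shape[0]:
        raise ValueError("labels do not align with ratio profile samples")
    g = groups.n_groups
    test = "WR" if g == 2 else "KW"
    if exact is None:
        exact = bool(groups.group_sizes.max() < 20)

    keep_taxa = list(range(len(rp.taxon_ids)))
    if not include_reference:
        ref = set(rp.reference_taxa)
        keep_taxa = [j for j in keep_taxa if rp.taxon_ids[j] not in ref]

    stats_, pvals, constant = [], [], []
    for j in keep_taxa:
        col = rp.ratios[:, j]
        if np.ptp(col) == 0:
            stats_.append(np.nan)
            pvals.append(1.0)
            constant.append(True)
            continue
        s, p = _rank_test(col, groups.codes, g, exact)
        stats_.append(s)
        pvals.append(p)
        constant.append(False)

    qvals = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "taxon": [rp.taxon_ids[j] for j in keep_taxa],
            "statistic": stats_,
            "pvalue": pvals,
            "qvalue": qvals,
            "da_call": qvals <= fdr_target,
            "constant": constant,
            "in_reference": [rp.taxon_ids[j] in set(rp.reference_taxa) for j in keep_taxa],
        }
    )
    return DAResult(table=table, test=test, fdr_target=fdr_target)
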