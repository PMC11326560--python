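"""Sequential removal and random amalgamation: the reference-set search.

Starting from the full taxon set, each step scores candidate removals by
the MSS statistic and discards the candidate whose removal leaves the
groups looking most alike in log-ratio.  The chain stops when the best
MSS drops below a permutation-null threshold (see
:mod:`optimem.nullref`) or when fewer than ``floor_frac`` of the
original taxa remain.  The surviving taxa are the non-DA reference set
whose per-sample sum serves as the normalizing denominator downstream.

Two modes: supervised (observed group labels) and unsupervised, where
labels are first derived by k-medoids clustering of the samples.

Default parameters follow the tool's operating heuristics: below 1000
taxa, remove one taxon per step (every single-taxon removal is a
candidate, so B equals the current taxon count) with R = max(1000, 2p)
amalgamations; above 1000 taxa, a two-stage plan first prunes with
fraction-mode removal and then refines the survivors in single-taxon
mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._engine import step_mss
from ._kmedoids import pam
from .core import GroupLabels, TaxonomicProfile, TaxonSubset
from .mss import MssValue
from .nullref import NullDistribution, build_null, classify_outcome, stopping_threshold

__all__ = [
    "SearchConfig",
    "TwoStagePlan",
    "StepRecord",
    "RemovalTrace",
    "ReferenceSet",
    "default_params",
    "removal_step",
    "run_optimem",
    "run_optimem_unsupervised",
    "cluster_samples",
]


@dataclass
class SearchConfig:
    """Tunable parameters of the sequential-removal search.

    ``eta`` is the fraction of taxa removed per step; ``None`` (or any
    value at or below 1/p) selects single-taxon mode, in which every
    single-taxon removal is a candidate and ``B`` is ignored.
    ``taxa_per_step`` is an integer alias for fraction mode ("remove
    this many taxa per step").
    """

    eta: float | None = None
    taxa_per_step: int | None = None
    B: int | None = None
    R: int = 1000
    stop_mode: str = "percentile"
    alpha: float = 0.05
    floor_frac: float = 0.10
    n_perm: int = 20
    zero_replacement: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta is not None and not 0 < self.eta < 1:
            raise ValueError("eta must be in (0, 1)")
        if self.taxa_per_step is not None and self.taxa_per_step < 1:
            raise ValueError("taxa_per_step must be >= 1")
        if self.B is not None and self.B < 1:
            raise ValueError("B must be >= 1")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.stop_mode not in ("percentile", "mean"):
            raise ValueError("stop_mode must be 'percentile' or 'mean'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.floor_frac < 1:
            raise ValueError("floor_frac must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def single_taxon_mode(self, p: int) -> bool:
        if self.taxa_per_step is not None:
            return self.taxa_per_step == 1
        return self.eta is None or self.eta <= 1.0 / p

    def removal_size(self, p_current: int) -> int:
        """Taxa removed per step in fraction mode."""
        if self.taxa_per_step is not None:
            return min(self.taxa_per_step, p_current - 1)
        kept = int(math.floor((1.0 - self.eta) * p_current))
        return max(1, p_current - kept)


@dataclass
class TwoStagePlan:
    """Coarse-then-fine plan for large taxon sets (p > 1000)."""

    stage1: SearchConfig
    p: int

    def stage2(self, p_survivors: int) -> SearchConfig:
        return replace(
            self.stage1,
            eta=None,
            taxa_per_step=None,
            B=None,
            R=max(2 * p_survivors, 1000),
        )


@dataclass
class StepRecord:
    k: int
    best_b: int
    removed_ids: list[str]
    q_best: float


@dataclass
class RemovalTrace:
    steps: list[StepRecord] = field(default_factory=list)
    threshold: float = float("nan")
    outcome: str = ""

    @property
    def q_values(self) -> np.ndarray:
        return np.array([s.q_best for s in self.steps])


@dataclass
class ReferenceSet:
    """Surviving non-DA taxa and the audit trail that produced them."""

    taxa: list[str]
    indices: np.ndarray
    final_q: float
    trace: RemovalTrace
    mode: str
    outcome: str
    threshold: float
    null: NullDistribution

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.outcome == "ref_found" and len(self.taxa) == 0:
            raise ValueError("ref_found outcome with an empty reference set")


def default_params(p: int, seed: int = 0) -> SearchConfig | TwoStagePlan:
    """Operating defaults by taxon count.

    p <= 1000: single-taxon removal, R = max(1000, 2p).  p > 1000: a
    :class:`TwoStagePlan` whose first stage removes a 1 % fraction per
    step with B = 2p + 1 candidate subsets and R = 2p, and whose second
    stage reruns the survivors in single-taxon mode.
    """
    if p < 5:
        raise ValueError("need at least 5 taxa")
    if p <= 1000:
        return SearchConfig(eta=None, B=None, R=max(1000, 2 * p), seed=seed)
    stage1 = SearchConfig(eta=0.01, B=2 * p + 1, R=2 * p, seed=seed)
    return TwoStagePlan(stage1=stage1, p=p)


def _candidates_for_step(
    p_current: int, cfg: SearchConfig, k: int
) -> list[np.ndarray]:
    if cfg.single_taxon_mode(p_current):
        return [np.array([j]) for j in range(p_current)]
    m = cfg.removal_size(p_current)
    B = cfg.B if cfg.B is not None else p_current
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 555_444_333, k]))
    return [np.sort(rng.choice(p_current, size=m, replace=False)) for _ in range(B)]


def _step_q(
    M_cur: np.ndarray,
    indicator: np.ndarray,
    sizes: np.ndarray,
    candidates: list[np.ndarray],
    cfg: SearchConfig,
    k: int,
    context: int = 0,
) -> np.ndarray:
    p_cur = M_cur.shape[1]
    evaluable = [c for c in candidates if p_cur - c.size >= 2]
    q = np.full(len(candidates), np.inf)
    if evaluable:
        q_eval = step_mss(
            M_cur, indicator, sizes, evaluable, cfg.R,
            master_seed=cfg.seed, context=context, k=k,
            zero_replacement=cfg.zero_replacement,
        )
        j = 0
        for i, c in enumerate(candidates):
            if p_cur - c.size >= 2:
                q[i] = q_eval[j]
                j += 1
    return q


def removal_step(
    profile: TaxonomicProfile,
    groups: GroupLabels,
    cfg: SearchConfig,
    k: int = 1,
) -> tuple[int, TaxonSubset, MssValue]:
    """Score one removal step and return the winning candidate.

    In single-taxon mode the candidates are exactly the current
    single-taxon removals; otherwise B random eta-fraction removals.
    Ties in the argmin go to the lowest candidate index.
    """
    p = profile.n_taxa
    if p < 2:
        raise ValueError("need at least 2 taxa to remove from")
    candidates = _candidates_for_step(p, cfg, k)
    q = _step_q(
        profile.abundance, groups.indicator(), groups.group_sizes.astype(float),
        candidates, cfg, k,
    )
    best = int(np.argmin(q))
    keep = np.setdiff1d(np.arange(p), candidates[best])
    return best, TaxonSubset(keep=keep, k=k), MssValue(
        Q=float(q[best]), k=k, b=best, R=cfg.R
    )


def run_optimem(
    profile: TaxonomicProfile,
    groups: GroupLabels,
    cfg: SearchConfig | TwoStagePlan | None = None,
    _mode: str = "supervised",
) -> ReferenceSet:
    """Full sequential removal and random amalgamation search.

    Builds the permutation null, iterates removal steps, and stops when
    the best MSS is at or below the stopping threshold or fewer than
    ``floor_frac`` of the taxa remain.  If the very first best MSS is
    already at or below the null upper limit, the groups are
    indistinguishable from shuffled labels: all taxa are retained and
    the outcome is ``no_da_taxa``.  Fully reproducible given
    ``cfg.seed``.
    """
    profile.validate_for_analysis()
    if groups.codes.size != profile.n_samples:
        raise ValueError("labels do not align with profile samples")
    p = profile.n_taxa
    if cfg is None:
        cfg = default_params(p)
    if isinstance(cfg, TwoStagePlan):
        return _run_two_stage(profile, groups, cfg, _mode)

    M = profile.abundance
    indicator = groups.indicator()
    sizes = groups.group_sizes.astype(float)
    B_null = p if cfg.single_taxon_mode(p) else (cfg.B or p)
    null = build_null(
        profile, groups, B=B_null, R=cfg.R, n_perm=cfg.n_perm, seed=cfg.seed,
        eta=cfg.eta, alpha=cfg.alpha, zero_replacement=cfg.zero_replacement,
    )
    threshold = stopping_threshold(null, cfg.stop_mode, cfg.alpha)

    keep = np.arange(p)
    floor_count = cfg.floor_frac * p
    trace = RemovalTrace(threshold=threshold)
    first_q = math.inf
    final_q = math.inf
    floor_reached = False
    k = 0
    while True:
        k += 1
        candidates = _candidates_for_step(keep.size, cfg, k)
        q = _step_q(M[:, keep], indicator, sizes, candidates, cfg, k)
        best = int(np.argmin(q))
        q_best = float(q[best])
        removed_local = candidates[best]
        removed_ids = [profile.taxon_ids[keep[j]] for j in removed_local]
        trace.steps.append(StepRecord(k=k, best_b=best, removed_ids=removed_ids, q_best=q_best))
        if k == 1:
            first_q = q_best
            if first_q <= null.upper_limit:
                # Indistinguishable from shuffled labels: keep everything.
                final_q = first_q
                break
        keep = np.delete(keep, removed_local)
        final_q = q_best
        if q_best <= threshold:
            break
        if keep.size < floor_count or keep.size < 2:
            floor_reached = True
            break

    outcome = classify_outcome(first_q, null, floor_reached, trace.q_values)
    if outcome == "no_da_taxa" and len(trace.steps) == 1:
        keep = np.arange(p)
    if floor_reached:
        warnings.warn(
            "sequential removal hit the taxon floor without reaching the "
            "stopping criterion; all remaining taxa may be differentially "
            "abundant",
            stacklevel=2,
        )
    trace.outcome = outcome
    return ReferenceSet(
        taxa=[profile.taxon_ids[j] for j in keep],
        indices=keep,
        final_q=final_q,
        trace=trace,
        mode=_mode,
        outcome=outcome,
        threshold=threshold,
        null=null,
    )


def _run_two_stage(
    profile: TaxonomicProfile,
    groups: GroupLabels,
    plan: TwoStagePlan,
    mode: str,
) -> ReferenceSet:
    stage1 = run_optimem(profile, groups, plan.stage1, _mode=mode)
    if stage1.outcome != "ref_found" or len(stage1.taxa) < 5:
        return stage1
    from .core import select_subset

    sub = select_subset(profile, TaxonSubset(keep=stage1.indices))
    stage2 = run_optimem(sub, groups, plan.stage2(len(stage1.taxa)), _mode=mode)
    # Re-express survivors in the original profile's indices.
    idx = stage1.indices[stage2.indices]
    return replace(stage2, indices=idx)


def cluster_samples(
    profile: TaxonomicProfile,
    n_clusters: int,
    seed: int = 0,
    metric: str = "braycurtis",
) -> GroupLabels:
    """Group samples by k-medoids (PAM) on their compositions.

    ``metric='braycurtis'`` computes Bray–Curtis dissimilarity on closed
    proportions (the default); ``metric='clr'`` uses Euclidean distance
    on centered log-ratio transformed proportions with a half-count
    pseudocount.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    M = profile.abundance
    prop = M / M.sum(axis=1, keepdims=True)
    if metric == "braycurtis":
        d = squareform(pdist(prop, metric="braycurtis"))
    elif metric == "clr":
        logged = np.log(np.where(prop == 0, 0.5 / M.sum(axis=1, keepdims=True), prop))
        clr = logged - logged.mean(axis=1, keepdims=True)
        d = squareform(pdist(clr, metric="euclidean"))
    else:
        raise ValueError("metric must be 'braycurtis' or 'clr'")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 222_111_000]))
    last_sizes = None
    for _ in range(10):
        labels = pam(d, n_clusters, rng=rng)
        last_sizes = np.bincount(labels, minlength=n_clusters)
        if last_sizes.min() >= 2:
            return GroupLabels(
                codes=labels,
                group_names=[f"cluster{i}" for i in range(n_clusters)],
                source="clustered",
            )
    raise RuntimeError(
        f"k-medoids produced a cluster with fewer than 2 samples "
        f"(sizes {last_sizes}); check n_clusters"
    )


def run_optimem_unsupervised(
    profile: TaxonomicProfile,
    n_clusters: int,
    cfg: SearchConfig | TwoStagePlan | None = None,
    metric: str = "braycurtis",
) -> ReferenceSet:
    """Reference search without observed labels.

    Samples are first clustered by k-medoids on Bray–Curtis distances
    (an approximation to exhaustively searching for the sample
    partition with the largest first-step MSS), then the supervised
    search runs on the cluster labels.
    """
    seed = 0
    if isinstance(cfg, SearchConfig):
        seed = cfg.seed
    elif isinstance(cfg, TwoStagePlan):
        seed = cfg.stage1.seed
    groups = cluster_samples(profile, n_clusters, seed=seed, metric=metric)
    return run_optimem(profile, groups, cfg, _mode="unsupervised")
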