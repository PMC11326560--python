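import numpy as np
import pytest

from optimem import (
    SearchConfig,
    TwoStagePlan,
    cluster_samples,
    default_params,
    removal_step,
    run_optimem,
    run_optimem_unsupervised,
)

from conftest import make_profile, two_groups


def da_profile(seed=0, n_per_group=15, p=12, n_da=3, fold=4.0):
    """Poisson counts; the first n_da taxa are scaled in group 2."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(50, 300, size=p)
    counts = rng.poisson(mu, size=(2 * n_per_group, p)).astype(float)
    counts[n_per_group:, :n_da] = rng.poisson(
        mu[:n_da] * fold, size=(n_per_group, n_da)
    )
    return make_profile(counts), two_groups(n_per_group), np.arange(n_da)


class TestSearchConfig:
    def test_single_taxon_mode(self):
        cfg = SearchConfig()
        assert cfg.single_taxon_mode(100)
        cfg = SearchConfig(eta=0.005)
        assert cfg.single_taxon_mode(100)  # 0.005 <= 1/100
        cfg = SearchConfig(eta=0.05)
        assert not cfg.single_taxon_mode(100)
        assert cfg.removal_size(100) == 5

    def test_taxa_per_step_alias(self):
        cfg = SearchConfig(taxa_per_step=3)
        assert not cfg.single_taxon_mode(50)
        assert cfg.removal_size(50) == 3
        assert cfg.removal_size(3) == 2  # never removes everything

    def test_validation(self):
        with pytest.raises(ValueError):
            SearchConfig(eta=1.5)
        with pytest.raises(ValueError):
            SearchConfig(R=0)
        with pytest.raises(ValueError):
            SearchConfig(stop_mode="nope")
        with pytest.raises(ValueError):
            SearchConfig(floor_frac=0.0)


class TestDefaultParams:
    def test_small_p(self):
        cfg = default_params(100)
        assert isinstance(cfg, SearchConfig)
        assert cfg.R == 1000
        cfg = default_params(800)
        assert cfg.R == 1600

    def test_large_p_two_stage(self):
        plan = default_params(1500)
        assert isinstance(plan, TwoStagePlan)
        assert plan.stage1.eta == pytest.approx(0.01)
        assert plan.stage1.B == 3001
        assert plan.stage1.R == 3000
        stage2 = plan.stage2(200)
        assert stage2.eta is None and stage2.R == 1000

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            default_params(4)


class TestRemovalStep:
    def test_removes_da_taxon_noiseless(self):
        # Noiseless means: group 2 doubles taxon 0 only.  Removing taxon
        # 0 makes the groups compositionally identical, so its candidate
        # must win by a wide margin.
        base = np.tile(np.array([30.0, 20, 25, 40, 15, 10]), (6, 1))
        doubled = base.copy()
        doubled[:, 0] *= 2
        prof = make_profile(np.vstack([base, doubled]))
        groups = two_groups(6)
        cfg = SearchConfig(R=100, seed=0)
        best, subset, q = removal_step(prof, groups, cfg)
        assert best == 0
        assert 0 not in subset.keep
        assert q.Q == pytest.approx(0.0, abs=1e-18)

    def test_two_taxa_edge(self):
        # Removing either taxon leaves one, which cannot be partitioned:
        # every candidate is inf and the tie goes to the lowest index.
        prof = make_profile(np.arange(1.0, 9.0).reshape(4, 2))
        groups = two_groups(2)
        best, subset, q = removal_step(prof, groups, SearchConfig(R=10))
        assert best == 0
        assert np.isinf(q.Q)

    def test_fraction_mode_candidates(self):
        prof, groups, _ = da_profile(p=20)
        cfg = SearchConfig(eta=0.2, B=7, R=50, seed=5)
        best, subset, q = removal_step(prof, groups, cfg)
        assert len(subset.keep) == 16  # removed floor(0.2*20)=4
        assert 0 <= best < 7


class TestRunOptimem:
    def test_recovers_non_da_taxa(self):
        prof, groups, da = da_profile(seed=3, fold=5.0)
        ref = run_optimem(prof, groups, SearchConfig(R=300, seed=3))
        assert ref.outcome == "ref_found"
        # The strong DA taxa must be gone from the reference.
        assert not set(f"t{j + 1}" for j in da) & set(ref.taxa)
        assert len(ref.taxa) >= 6

    def test_deterministic(self):
        prof, groups, _ = da_profile(seed=4)
        a = run_optimem(prof, groups, SearchConfig(R=200, seed=11))
        b = run_optimem(prof, groups, SearchConfig(R=200, seed=11))
        assert a.taxa == b.taxa
        assert np.array_equal(a.trace.q_values, b.trace.q_values)
        assert a.threshold == b.threshold

    def test_no_da_on_pure_null(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(100, size=(20, 10)).astype(float)
        prof = make_profile(counts)
        ref = run_optimem(prof, two_groups(10), SearchConfig(R=200, seed=8))
        assert ref.outcome == "no_da_taxa"
        assert len(ref.taxa) == 10  # everything retained

    def test_floor_warns_when_everything_differs(self):
        # Every taxon's relative level differs between groups by at
        # least 2x (widely spaced scale factors), so no subset can ever
        # look non-differential and the search must hit the floor.
        rng = np.random.default_rng(1)
        mu = np.full(10, 200.0)
        g1 = rng.poisson(mu, size=(8, 10)).astype(float)
        g2 = rng.poisson(mu * np.geomspace(1, 1000, 10), size=(8, 10)).astype(float)
        prof = make_profile(np.vstack([g1, g2]))
        with pytest.warns(UserWarning, match="floor"):
            ref = run_optimem(prof, two_groups(8), SearchConfig(R=100, seed=2))
        assert ref.outcome == "all_da_taxa"

    def test_label_alignment_checked(self):
        prof, groups, _ = da_profile()
        bad = two_groups(4)
        with pytest.raises(ValueError, match="align"):
            run_optimem(prof, bad, SearchConfig(R=10))

    def test_monotone_trend_high_snr(self):
        # With strong heterogeneous signal the best-Q trace should be
        # non-increasing over its first half.  (Equal folds behave
        # differently: a shrinking equal-fold DA set raises the
        # partition-to-partition spread before it vanishes.)
        hits = 0
        folds = [12.0, 6.0, 3.0, 2.0]
        for seed in range(5):
            rng = np.random.default_rng(seed)
            mu = rng.uniform(50, 300, size=14)
            counts = rng.poisson(mu, size=(30, 14)).astype(float)
            for j, f in enumerate(folds):
                counts[15:, j] = rng.poisson(mu[j] * f, size=15)
            prof = make_profile(counts)
            ref = run_optimem(prof, two_groups(15), SearchConfig(R=300, seed=seed))
            q = ref.trace.q_values
            half = q[: max(2, len(q) // 2)]
            if np.all(np.diff(half) <= 1e-12):
                hits += 1
        assert hits >= 4


class TestUnsupervised:
    def test_cluster_samples_recovers_groups(self):
        prof, groups, _ = da_profile(seed=6, n_per_group=12, fold=8.0)
        labels = cluster_samples(prof, 2, seed=6)
        assert labels.source == "clustered"
        # Clustering is label-invariant: compare up to relabeling.
        agreement = np.mean(labels.codes == groups.codes)
        assert max(agreement, 1 - agreement) >= 0.9

    def test_unsupervised_runs(self):
        prof, groups, da = da_profile(seed=7, n_per_group=12, fold=8.0)
        ref = run_optimem_unsupervised(prof, 2, SearchConfig(R=200, seed=7))
        assert ref.mode == "unsupervised"
        assert ref.outcome in ("ref_found", "no_da_taxa", "all_da_taxa")

    def test_bad_metric(self):
        prof, _, _ = da_profile()
        with pytest.raises(ValueError, match="metric"):
            cluster_samples(prof, 2, metric="cosine")


class TestTwoStage:
    def test_two_stage_runs_and_reindexes(self):
        # Shrunk version of the large-p plan: fraction-mode stage 1 then
        # single-taxon stage 2 on the survivors.
        prof, groups, da = da_profile(seed=9, n_per_group=12, p=30, n_da=5, fold=6.0)
        stage1 = SearchConfig(eta=0.1, B=15, R=150, seed=9)
        plan = TwoStagePlan(stage1=stage1, p=30)
        ref = run_optimem(prof, groups, plan)
        assert set(ref.indices.tolist()) <= set(range(30))
        if ref.outcome == "ref_found":
            kept_names = {prof.taxon_ids[j] for j in ref.indices}
            assert len(kept_names & {f"t{j + 1}" for j in da}) <= 2
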