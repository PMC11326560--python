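import numpy as np
import pytest

from optimem import (
    SimulationDesign,
    design_basic,
    design_scenario,
    make_ln_covariance,
    max_subcompositionally_equivalent_set,
    permute_labels,
    score_calls,
    simulate,
    simulate_ln,
    simulate_nb,
)


class TestDesignBasic:
    def test_balance_constraint(self):
        for seed in range(5):
            d = design_basic(50, 2, 10, n_da_range=(5, 15), balance="balance", rng=np.random.default_rng(seed))
            s = d.da_sums()
            assert abs(s[1] - s[0]) <= 0.05 * s[0]

    def test_unbalance_constraint(self):
        d = design_basic(50, 2, 10, n_da_range=(5, 15), balance="unbalance", rng=np.random.default_rng(0))
        s = d.da_sums()
        assert s.max() / s.min() >= 2.0

    def test_da_count_within_range(self):
        d = design_basic(
            100, 2, 10, n_da_range=(5, 50), rng=np.random.default_rng(1)
        )
        assert 5 <= d.da_flags.sum() <= 50
        assert np.all(d.mu[0, ~d.da_flags] == d.mu[1, ~d.da_flags])

    def test_mixed_modes_three_groups(self):
        d = design_basic(
            60, 3, 10, n_da_range=(5, 20), balance=["balance", "unbalance"],
            rng=np.random.default_rng(2),
        )
        flags = d.da_flags
        s = d.mu[:, flags].sum(axis=1)
        assert abs(s[1] - s[0]) <= 0.05 * s[0]
        assert max(s[2], s[0]) / min(s[2], s[0]) >= 2.0

    def test_bad_range(self):
        with pytest.raises(ValueError):
            design_basic(20, 2, 10, n_da_range=(1, 19))


class TestDesignScenarios:
    def test_scenario1_block_and_balance(self):
        rng = np.random.default_rng(3)
        d = design_scenario(1, rng=rng)
        s = d.da_sums()
        assert abs(s[1] - s[0]) <= 0.05 * s[0]
        blocks = d.extras["equivalent_blocks"]
        assert len(blocks) == 2
        for block in blocks:
            sub = d.mu[:, np.array(block)]
            closed = sub / sub.sum(axis=1, keepdims=True)
            assert np.allclose(closed[0], closed[1])

    def test_scenario2_unbalanced_block(self):
        d = design_scenario(2, rng=np.random.default_rng(4))
        s = d.da_sums()
        assert s.max() / s.min() >= 2.0
        assert len(d.extras["equivalent_blocks"]) == 1

    def test_scenario3_majority_violation(self):
        d = design_scenario(3, rng=np.random.default_rng(5))
        flags = d.da_flags
        assert flags.sum() > 50
        fc = d.fold_changes[flags]
        assert np.all(fc >= 2.0 - 1e-9)
        s = d.da_sums()
        assert 2.0 <= s.max() / s.min() <= 2.5 + 1e-9

    def test_scenario_solvable_at_small_p(self):
        # At diagnostic scale, the constructed means must satisfy the
        # identifiability requirement the scenarios are designed around.
        rng = np.random.default_rng(6)
        d = design_scenario(1, p=14, block_size=3, n_extra_da=2, rng=rng)
        _, s_max, holds = max_subcompositionally_equivalent_set(d.mu)
        assert holds

    def test_invalid_scenario(self):
        with pytest.raises(ValueError):
            design_scenario(4)

    def test_verifier_rejects_broken_design(self):
        d = design_scenario(3, rng=np.random.default_rng(7))
        mu = d.mu.copy()
        mu[1] = mu[0]  # no DA taxa at all
        with pytest.raises(ValueError, match="majority"):
            SimulationDesign(
                p=d.p, G=2, n_per_group=d.n_per_group, model="nb",
                mu=mu, dispersion=d.dispersion, scenario="scenario3",
            )


class TestSimulateNb:
    def test_deterministic(self):
        d = design_basic(20, 2, 8, n_da_range=(3, 6), rng=np.random.default_rng(8))
        a = simulate_nb(d, 99)
        b = simulate_nb(d, 99)
        assert np.array_equal(a.profile.abundance, b.profile.abundance)

    def test_poisson_limit_mean(self):
        mu = np.array([[50.0, 200.0], [50.0, 200.0]])
        d = SimulationDesign(
            p=2, G=2, n_per_group=[2500, 2500], model="nb", mu=mu,
            dispersion=np.zeros(2), depth_sigma=0.0,
        )
        ds = simulate_nb(d, 1)
        got = ds.profile.abundance.mean(axis=0)
        assert np.all(np.abs(got - mu[0]) / mu[0] < 0.02)

    def test_nb_moments(self):
        phi = 0.4
        mu = np.array([[100.0], [100.0]])
        d = SimulationDesign(
            p=1, G=2, n_per_group=[4000, 4000], model="nb", mu=mu,
            dispersion=np.array([phi]), depth_sigma=0.0,
        )
        ds = simulate_nb(d, 2)
        x = ds.profile.abundance[:, 0]
        expected_var = 100 + phi * 100**2
        assert x.mean() == pytest.approx(100, rel=0.05)
        assert x.var() == pytest.approx(expected_var, rel=0.15)

    def test_wrong_model_rejected(self):
        d = design_basic(10, 2, 4, n_da_range=(2, 4), model="nb", rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_ln(d, 0)


class TestSimulateLn:
    def make_design(self, p=10, rng=None, cov=None):
        rng = rng or np.random.default_rng(9)
        d = design_basic(p, 2, 8, n_da_range=(2, 5), model="ln", rng=rng)
        if cov is not None:
            d.cov = cov
        return d

    def test_degenerate_covariance(self):
        d = self.make_design(cov=np.zeros((10, 10)))
        ds = simulate_ln(d, 3, integer_counts=False)
        prop = ds.profile.abundance / ds.profile.abundance.sum(axis=1, keepdims=True)
        expected = d.mu[0] / d.mu[0].sum()
        g1 = prop[: 8]
        assert np.allclose(g1, expected, rtol=1e-10)

    def test_positive_correlation_preserved(self):
        p = 6
        cov = np.eye(p) * 0.5
        cov[0, 1] = cov[1, 0] = 0.45
        mu = np.tile(np.full(p, 100.0), (2, 1))
        d = SimulationDesign(
            p=p, G=2, n_per_group=[400, 400], model="ln", mu=mu, cov=cov,
        )
        ds = simulate_ln(d, 4, integer_counts=False)
        logp = np.log(
            ds.profile.abundance / ds.profile.abundance.sum(axis=1, keepdims=True)
        )
        r = np.corrcoef(logp[:, 0], logp[:, 1])[0, 1]
        assert r > 0.3

    def test_non_pd_covariance_rejected(self):
        cov = -np.eye(10)
        d = self.make_design(cov=cov)
        with pytest.raises(ValueError, match="positive definite"):
            simulate_ln(d, 0)

    def test_integer_counts(self):
        d = self.make_design()
        ds = simulate_ln(d, 5)
        assert np.all(ds.profile.abundance == np.round(ds.profile.abundance))


class TestMakeLnCovariance:
    def test_positive_definite_and_deterministic(self):
        a = make_ln_covariance(20, np.random.default_rng(10))
        b = make_ln_covariance(20, np.random.default_rng(10))
        assert np.array_equal(a, b)
        eig = np.linalg.eigvalsh(a)
        assert eig.min() > 0

    def test_variance_range(self):
        cov = make_ln_covariance(50, np.random.default_rng(11), var_range=(1.0, 3.0))
        v = np.diag(cov)
        assert v.min() >= 1.0 - 1e-9 and v.max() <= 3.0 + 1e-9


class TestPermuteLabels:
    def test_label_multiset_preserved(self):
        rng = np.random.default_rng(12)
        d = design_basic(15, 2, 6, n_da_range=(2, 5), rng=rng)
        ds = simulate(d, rng)
        null = permute_labels(ds, 13)
        assert sorted(null.groups.codes) == sorted(ds.groups.codes)
        assert not null.da_flags.any()

    def test_deterministic(self):
        rng = np.random.default_rng(14)
        ds = simulate(design_basic(15, 2, 6, n_da_range=(2, 5), rng=rng), rng)
        a = permute_labels(ds, 7)
        b = permute_labels(ds, 7)
        assert np.array_equal(a.groups.codes, b.groups.codes)


class TestScoreCalls:
    def test_perfect(self):
        truth = np.array([True, False, True])
        assert score_calls(truth, truth) == (1.0, 0.0, 0.0)

    def test_empty_discovery(self):
        truth = np.array([True, False])
        calls = np.array([False, False])
        tpr, fdr, fpr = score_calls(calls, truth)
        assert (tpr, fdr, fpr) == (0.0, 0.0, 0.0)

    def test_hand_example(self):
        # TP=2, FP=1, FN=2, TN=5
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        calls = np.array([1, 1, 0, 0, 1, 0, 0, 0, 0, 0], dtype=bool)
        tpr, fdr, fpr = score_calls(calls, truth)
        assert tpr == pytest.approx(0.5)
        assert fdr == pytest.approx(1 / 3)
        assert fpr == pytest.approx(1 / 6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score_calls([True], [True, False])
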