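import numpy as np
import pytest

from palm.simulate import (
    SimConfig,
    choose_active,
    make_baseline,
    make_correlated,
    simulate_meta_experiment,
    simulate_study,
    spike_in,
)


class TestBaseline:
    def test_valid_proportions(self, rng):
        mu = make_baseline(400, rng)
        assert mu.shape == (400,)
        assert (mu > 0).all()
        assert abs(mu.sum() - 1) < 1e-12

    def test_sigma_zero_limit_is_uniform(self, rng):
        mu = make_baseline(2, rng, log_sd=1e-12)
        np.testing.assert_allclose(mu, [0.5, 0.5], atol=1e-9)

    def test_abundant_fraction_calibration(self):
        """Median fraction of features above 1e-3 is in the realistic band."""
        fracs = [
            (make_baseline(401, np.random.default_rng(s), 2.5) >= 1e-3).mean()
            for s in range(1000)
        ]
        assert 0.05 <= np.median(fracs) <= 0.30

    def test_too_few_features_rejected(self, rng):
        with pytest.raises(ValueError):
            make_baseline(1, rng)


class TestChooseActive:
    def test_half_abundant_half_rare(self, rng):
        mu = np.concatenate([np.full(60, 0.015), np.full(40, 0.0025 / 40)])
        mu = mu / mu.sum()
        idx, signs = choose_active(mu, 0.1, 1e-3, rng)
        assert idx.size == 10 and signs.size == 10
        assert (mu[idx] >= 1e-3).sum() == 5
        assert (mu[idx] < 1e-3).sum() == 5

    def test_positive_scheme_all_positive(self, rng):
        mu = np.concatenate([np.full(50, 0.0195), np.full(50, 5e-4)])
        _, signs = choose_active(mu, 0.1, 1e-3, rng, effect_direction="positive")
        assert (signs == 1).all()

    def test_insufficient_stratum_rejected(self, rng):
        mu = np.concatenate([np.full(3, 0.33), np.full(97, 0.01 / 97)])
        with pytest.raises(ValueError, match="abundant"):
            choose_active(mu / mu.sum(), 0.1, 1e-3, rng)


class TestSpikeIn:
    def test_no_active_features_identity(self):
        mu = np.array([0.5, 0.3, 0.2])
        mu0, mu1 = spike_in(mu, np.array([], dtype=int), np.array([]), np.array([]))
        np.testing.assert_array_equal(mu0, mu)
        np.testing.assert_array_equal(mu1, mu)

    def test_hand_renormalisation(self):
        mu = np.array([0.5, 0.3, 0.2])
        mu0, mu1 = spike_in(mu, np.array([0]), np.array([2.0]), np.array([1.0]))
        np.testing.assert_allclose(mu1, np.array([1.0, 0.3, 0.2]) / 1.5, atol=1e-12)
        np.testing.assert_allclose(mu0, mu, atol=1e-12)

    def test_negative_sign_inflates_reference_group(self):
        mu = np.array([0.5, 0.3, 0.2])
        mu0, mu1 = spike_in(mu, np.array([1]), np.array([3.0]), np.array([-1.0]))
        np.testing.assert_allclose(mu0, np.array([0.5, 0.9, 0.2]) / 1.6, atol=1e-12)
        np.testing.assert_allclose(mu1, mu, atol=1e-12)

    def test_inactive_ra_shifts_but_sums_hold(self, rng):
        mu = rng.dirichlet(np.ones(20))
        mu0, mu1 = spike_in(mu, np.array([0, 1]), np.array([2.0, 3.0]),
                            np.array([1.0, 1.0]))
        assert abs(mu0.sum() - 1) < 1e-12 and abs(mu1.sum() - 1) < 1e-12
        # relative abundances of non-active features all shift
        assert (mu1[2:] < mu[2:]).all()


class TestSimulateStudy:
    def test_counts_sum_to_depths(self, rng):
        cfg = SimConfig(seed=0)
        mu = make_baseline(50, rng)
        table, design = simulate_study(mu, mu, 40, rng, cfg)
        np.testing.assert_array_equal(table.counts.sum(axis=1), table.depths)
        assert set(design.covariate) == {0.0, 1.0}
        assert (design.covariate == 1).sum() == 20

    def test_depth_floor_respected(self, rng):
        cfg = SimConfig(seed=0, depth_min=2000)
        mu = make_baseline(30, rng)
        table, _ = simulate_study(mu, mu, 60, rng, cfg)
        assert (table.depths >= 2000).all()

    def test_uneven_scheme_doubles_one_group(self):
        cfg = SimConfig(seed=0, depth_scheme="uneven")
        rng = np.random.default_rng(4)
        mu = make_baseline(30, rng)
        table, design = simulate_study(mu, mu, 200, rng, cfg)
        d0 = table.depths[design.covariate == 0].mean()
        d1 = table.depths[design.covariate == 1].mean()
        ratio = max(d0, d1) / min(d0, d1)
        assert 1.6 < ratio < 2.5

    def test_spiked_feature_mean_ra_ratio(self):
        """Group ratio of mean RA approaches the renormalised target."""
        rng = np.random.default_rng(9)
        cfg = SimConfig(seed=0, dirichlet_scale=50.0)
        mu = np.full(20, 0.05)
        mu0, mu1 = spike_in(mu, np.array([3]), np.array([5.0]), np.array([1.0]))
        table, design = simulate_study(mu0, mu1, 500, rng, cfg)
        ra = table.counts / table.depths[:, None]
        got = ra[design.covariate == 1, 3].mean() / ra[design.covariate == 0, 3].mean()
        target = mu1[3] / mu0[3]
        assert abs(got / target - 1) < 0.15


class TestMakeCorrelated:
    def test_mixing_arithmetic(self):
        """round((Y* + Y)/2) with ties to even."""
        np.testing.assert_array_equal(
            np.rint((np.array([0, 2]) + np.array([2, 0])) / 2.0), [1, 1]
        )

    def test_clusters_and_depths(self, rng):
        cfg = SimConfig(seed=0)
        mu = make_baseline(40, rng)
        table, design = simulate_study(mu, mu, 40, rng, cfg)
        ctable, cdesign = make_correlated(table, design, rng, mu, mu, cfg)
        assert cdesign.cluster_ids is not None
        _, sizes = np.unique(cdesign.cluster_ids, return_counts=True)
        assert (sizes == 2).all()
        np.testing.assert_array_equal(ctable.depths, ctable.counts.sum(axis=1))
        # clusters never straddle groups
        for c in np.unique(cdesign.cluster_ids):
            assert len(set(cdesign.covariate[cdesign.cluster_ids == c])) == 1

    def test_within_cluster_correlation_exceeds_between(self):
        """Mixing with a shared draw makes cluster members co-vary."""
        rng = np.random.default_rng(123)
        cfg = SimConfig(seed=0, dirichlet_scale=20.0)
        mu = make_baseline(30, np.random.default_rng(5))
        table, design = simulate_study(mu, mu, 400, rng, cfg)
        ctable, cdesign = make_correlated(table, design, rng, mu, mu, cfg)
        ra = ctable.counts / ctable.depths[:, None]
        feat = np.argsort(mu)[-1]  # most abundant feature
        v = ra[:, feat]
        cl = cdesign.cluster_ids
        within = [np.prod(v[cl == c] - v.mean()) for c in np.unique(cl)]
        rng2 = np.random.default_rng(7)
        perm = rng2.permutation(len(v))
        between = [
            (v[perm[2 * i]] - v.mean()) * (v[perm[2 * i + 1]] - v.mean())
            for i in range(len(v) // 2)
        ]
        assert np.mean(within) > np.mean(between)

    def test_odd_group_rejected(self, rng):
        cfg = SimConfig(seed=0)
        mu = make_baseline(10, rng)
        table, design = simulate_study(mu, mu, 6, rng, cfg)
        with pytest.raises(ValueError, match="divisible"):
            make_correlated(table, design, rng, mu, mu, cfg)


class TestMetaExperiment:
    def test_same_seed_bitwise_identical(self):
        cfg = SimConfig(n_studies=2, sample_sizes=(20, 20), n_features=30, seed=5)
        a, ta = simulate_meta_experiment(cfg)
        b, tb = simulate_meta_experiment(cfg)
        np.testing.assert_array_equal(ta.active_idx, tb.active_idx)
        np.testing.assert_array_equal(ta.folds, tb.folds)
        for (t1, d1), (t2, d2) in zip(a, b):
            np.testing.assert_array_equal(t1.counts, t2.counts)
            np.testing.assert_array_equal(d1.covariate, d2.covariate)

    def test_adding_a_study_preserves_earlier_baselines(self):
        """Per-study RNG streams are fixed offsets from the master seed."""
        cfg3 = SimConfig(n_studies=3, sample_sizes=(20, 20, 20), n_features=30, seed=5)
        cfg4 = SimConfig(n_studies=4, sample_sizes=(20, 20, 20, 20), n_features=30, seed=5)
        _, ta = simulate_meta_experiment(cfg3)
        _, tb = simulate_meta_experiment(cfg4)
        for m1, m2 in zip(ta.baselines, tb.baselines[:3]):
            np.testing.assert_array_equal(m1, m2)

    def test_truth_shared_across_studies(self):
        cfg = SimConfig(seed=11)
        studies, truth = simulate_meta_experiment(cfg)
        assert len(studies) == 5
        m = truth.active_idx.size
        assert m == round(0.1 * 92)
        assert truth.folds.shape == (m,) and ((truth.folds > 1) & (truth.folds <= 5)).all()
        eff = truth.true_log_effects(92)
        assert (eff[np.setdiff1d(np.arange(92), truth.active_idx)] == 0).all()
        np.testing.assert_allclose(
            np.abs(eff[truth.active_idx]), np.log(truth.folds), atol=1e-12
        )
        # baselines are study-specific
        assert not np.allclose(truth.baselines[0], truth.baselines[1])

    def test_active_count_rounding(self):
        cfg = SimConfig(n_studies=1, sample_sizes=(20,), n_features=92,
                        pi_active=0.1, seed=2)
        _, truth = simulate_meta_experiment(cfg)
        assert truth.active_idx.size == 9  # round(0.1 * 92)

    def test_odd_sample_size_rejected(self):
        with pytest.raises(ValueError, match="even"):
            SimConfig(n_studies=1, sample_sizes=(21,), seed=0)
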