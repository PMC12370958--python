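import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdpose.groupstats import (TreatmentResponseModel, classify_affected,
                               classify_tre, group_difference, kde,
                               kl_divergence, longitudinal_divergence,
                               normalise, score_task, score_tss)


class TestKde:
    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(0)
        est = kde(rng.normal(size=10000))
        at0 = np.interp(0.0, est.grid, est.density)
        assert at0 == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.1)

    def test_nonnegative_and_normalised(self):
        rng = np.random.default_rng(1)
        est = kde(rng.normal(size=500))
        assert np.all(est.density >= 0)
        assert np.trapezoid(est.density, est.grid) == pytest.approx(1.0,
                                                                    abs=0.02)

    def test_rescaled_support(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        a = kde(x)
        b = kde(2 * x)
        # doubling the data roughly doubles the support width
        wa = a.grid[-1] - a.grid[0]
        wb = b.grid[-1] - b.grid[0]
        assert wb == pytest.approx(2 * wa, rel=0.15)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            kde(np.ones(100))


class TestKlDivergence:
    def test_identity_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=1000)
        p = kde(x)
        assert abs(kl_divergence(p, p)) < 1e-6

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            mu = rng.uniform(-1, 1)
            p = kde(rng.normal(0, 1, 300))
            q = kde(rng.normal(mu, 1, 300))
            assert kl_divergence(p, q) >= -1e-9

    def test_two_normals_closed_form(self):
        # D(N(0,1) || N(1,1)) = 1/2
        rng = np.random.default_rng(5)
        p = kde(rng.normal(0, 1, 20000))
        q = kde(rng.normal(1, 1, 20000))
        assert kl_divergence(p, q) == pytest.approx(0.5, rel=0.15)

    def test_disjoint_supports_flagged(self):
        rng = np.random.default_rng(6)
        p = kde(rng.normal(0, 0.1, 300))
        q = kde(rng.normal(100, 0.1, 300))
        with pytest.raises(ValueError):
            kl_divergence(p, q)


class TestLongitudinalDivergence:
    def test_six_values_per_week(self):
        rng = np.random.default_rng(7)
        by_week = {w: rng.normal(size=300) for w in (0, 2, 4)}
        traj = longitudinal_divergence(by_week, seed=0)
        assert (traj.groupby("week").size() == 6).all()

    def test_stationary_feature_low_divergence(self):
        rng = np.random.default_rng(8)
        by_week = {w: rng.normal(size=400) for w in (0, 2, 4, 6)}
        traj = longitudinal_divergence(by_week, seed=1)
        assert traj.loc[traj.week > 0, "kl"].mean() < 0.05

    def test_drifting_feature_monotone(self):
        rng = np.random.default_rng(9)
        weeks = (0, 2, 4, 6, 8, 10)
        by_week = {w: rng.normal(2.0 * w / 10, 1.0, 400) for w in weeks}
        traj = longitudinal_divergence(by_week, seed=2)
        means = traj.groupby("week")["kl"].mean()
        rho, _ = stats.spearmanr(means.index, means.values)
        assert rho > 0.9

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            longitudinal_divergence({2: np.zeros(200)}, seed=0)


class TestNormalise:
    def test_arithmetic(self):
        np.testing.assert_allclose(normalise([2, 4, 6]), [0.0, 0.5, 1.0])

    def test_bounded(self):
        rng = np.random.default_rng(10)
        out = normalise(rng.normal(size=100))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_log_mode_preserves_order(self):
        out = normalise([1e-6, 1.0, 1e6], log=True)
        assert np.all(np.diff(out) > 0)

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(normalise([3.0, 3.0]), [0.0, 0.0])


class TestGroupDifference:
    def test_error_propagation(self):
        diff, sem = group_difference(1.2, 0.3, 1.0, 0.4)
        assert diff == pytest.approx(0.2)
        assert sem == pytest.approx(0.5)

    def test_equal_means(self):
        assert group_difference(1.0, 0.1, 1.0, 0.1)[0] == 0.0

    def test_antisymmetric(self):
        d1, s1 = group_difference(2.0, 0.2, 1.0, 0.1)
        d2, s2 = group_difference(1.0, 0.1, 2.0, 0.2)
        assert d1 == -d2 and s1 == s2


class TestTaskScores:
    def test_bwt_best_two_shortest(self):
        ts = score_task([10.0, 10.0, 30.0], [25.0, 25.0, 50.0], "BWT")
        assert ts.value == pytest.approx(250.0)
        assert not ts.excluded

    def test_identical_sessions_100(self):
        ts = score_task([8.0, 9.0, 10.0], [8.0, 9.0, 10.0], "RRT")
        assert ts.value == pytest.approx(100.0)

    def test_rrt_best_two_longest(self):
        ts = score_task([10.0, 20.0, 30.0], [20.0, 40.0, 60.0], "RRT")
        assert ts.value == pytest.approx(50.0 / 25.0 * 100.0)

    def test_bws_above_600_excluded(self):
        ts = score_task([10.0, 10.0], [70.0, 70.0], "BWT")
        assert ts.value == pytest.approx(700.0)
        assert ts.excluded and "type II" in ts.reason

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            score_task([10.0], [20.0, 20.0], "BWT")

    @pytest.mark.parametrize("incidences,expected", [
        ({1: [], 2: [3.0, 4.0], 3: [5.0, 3.0]}, 5),
        ({2: [3.0]}, 0),                           # one incidence only
        ({1: [3, 3], 2: [3, 3], 3: [3, 3]}, 6),    # all classes qualify
        ({1: [1.0, 1.5, 1.9]}, 0),                 # too short incidences
    ])
    def test_tss_arithmetic(self, incidences, expected):
        assert score_tss(incidences).value == expected


class TestClassifyAffected:
    def test_identical_samples_unaffected(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(20, 5))
        out = classify_affected(x, x.copy())
        assert not out["affected"].any()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(200):
            ct = rng.normal(0, 1, (20, 10))
            pd_ = rng.normal(0, 1, (20, 10))
            pd_[:, 0] += 3.0
            out = classify_affected(ct, pd_)
            hits += bool(out.loc[0, "affected"])
        assert hits / 200 >= 0.99

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(13)
        any_fp = 0
        n_sim = 500
        for _ in range(n_sim):
            ct = rng.normal(0, 1, (20, 20))
            pd_ = rng.normal(0, 1, (20, 20))
            any_fp += classify_affected(ct, pd_)["affected"].any()
        # FWER <= alpha (binomial slack on 500 simulations)
        assert any_fp / n_sim <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            classify_affected(np.zeros((2, 3)), np.zeros((5, 3)))


class TestClassifyTre:
    def _groups(self, seed, treated_shift, disease_shift=3.0, n=20):
        rng = np.random.default_rng(seed)
        ct = rng.normal(0, 1, (n, 1))
        dis = rng.normal(disease_shift, 1, (n, 1))
        tr = rng.normal(treated_shift, 1, (n, 1))
        return ct, dis, tr

    def test_treated_like_ct_is_completely_treated(self):
        hits = 0
        for seed in range(100):
            ct, dis, tr = self._groups(seed, treated_shift=0.0)
            out = classify_tre(ct, dis, tr)
            hits += out.loc[0, "category"] == "completely_treated"
        assert hits >= 95

    def test_treated_like_disease_is_untreated(self):
        hits = 0
        for seed in range(100):
            ct, dis, tr = self._groups(1000 + seed, treated_shift=3.0)
            out = classify_tre(ct, dis, tr)
            hits += out.loc[0, "category"] == "untreated"
        assert hits >= 95

    def test_midpoint_with_all_significant_is_partially_treated(self):
        # constructed case: all three pairwise shifts significant, mean between
        ct = np.zeros((20, 1)) + np.linspace(-0.5, 0.5, 20)[:, None]
        dis = 6.0 + np.linspace(-0.5, 0.5, 20)[:, None]
        tr = 3.0 + np.linspace(-0.5, 0.5, 20)[:, None]
        out = classify_tre(ct, dis, tr)
        assert out.loc[0, "category"] == "partially_treated"

    def test_overshoot_is_treat_associated(self):
        ct = np.linspace(-0.5, 0.5, 20)[:, None]
        dis = 6.0 + np.linspace(-0.5, 0.5, 20)[:, None]
        tr = -6.0 + np.linspace(-0.5, 0.5, 20)[:, None]
        out = classify_tre(ct, dis, tr)
        assert out.loc[0, "category"] == "treat_associated"

    def test_categories_exhaustive_exclusive(self):
        rng = np.random.default_rng(14)
        ct = rng.normal(0, 1, (15, 30))
        dis = rng.normal(rng.normal(0, 2, 30), 1, (15, 30))
        tr = rng.normal(rng.normal(0, 2, 30), 1, (15, 30))
        out = classify_tre(ct, dis, tr)
        assert out["category"].isin([
            "unaffected", "completely_treated", "partially_treated",
            "treat_associated", "untreated"]).all()
        assert len(out) == 30

    def test_model_results_summary(self):
        ct, dis, tr = self._groups(7, treated_shift=0.0)
        res = TreatmentResponseModel(ct, dis, tr).fit()
        assert res.category_fractions().sum() == pytest.approx(1.0)
        assert "completely_treated" in res.summary()
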