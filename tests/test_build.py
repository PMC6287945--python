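import warnings

import numpy as np
import pytest

from methage.build import (
    TrainConfig,
    evaluate_clock,
    resample_clocks,
    robustness_stats,
    train_clock,
)
from methage.qc import common_sites, soft_coverage_cutoff
from methage.simulate import SyntheticConfig, simulate_cohort
from methage.stats import mann_whitney_u
from methage.types import ClockDefinition, ClockEntry, CpGSite

from conftest import make_matrix


def small_cohort(seed=7, n_samples=60, n_sites=120, n_informative=12):
    cfg = SyntheticConfig(
        n_samples=n_samples, n_sites=n_sites, n_informative=n_informative,
        mean_depth=40, dropout_prob=0.0, seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, metadata, truth = simulate_cohort(cfg)
        matrix, _ = soft_coverage_cutoff(matrix)
        matrix, _ = common_sites(matrix, 0)
    return matrix, truth


FAST = TrainConfig(n_folds=4, n_lambda=40, seed=3)


class TestTrainClock:
    def test_beats_constant_predictor_on_heldout(self):
        matrix, _ = small_cohort()
        clock, report = train_clock(matrix, FAST)
        test_ages = np.array(
            [m.age_days for m in matrix.samples if m.sample_id in report.test_ids]
        )
        const_mae = np.abs(test_ages - matrix.ages.mean()).mean()
        assert report.mae_test < const_mae

    def test_report_consistent_with_stored_predictions(self):
        matrix, _ = small_cohort(seed=8)
        clock, report = train_clock(matrix, FAST)
        ages = {m.sample_id: m.age_days for m in matrix.samples}
        test_err = np.array(
            [abs(v - ages[k]) for k, v in report.test_predictions.items()]
        )
        assert report.mae_test == pytest.approx(test_err.mean(), abs=1e-9)
        train_err = np.array(
            [abs(v - ages[k]) for k, v in report.train_predictions.items()]
        )
        assert report.mae_train == pytest.approx(train_err.mean(), abs=1e-9)
        assert report.n_nonzero_sites == len(clock)

    def test_train_means_stored_as_percent(self):
        matrix, _ = small_cohort(seed=9)
        clock, report = train_clock(matrix, FAST)
        idx = matrix.site_index()
        train_rows = [matrix.sample_ids.index(s) for s in report.train_ids]
        for entry in clock.entries:
            col = matrix.pct[train_rows, idx[entry.site]]
            assert entry.train_mean == pytest.approx(col.mean())
            assert 0.0 <= entry.train_mean <= 100.0

    def test_log_days_response_uses_exp_transform(self):
        matrix, _ = small_cohort(seed=10)
        clock, report = train_clock(
            matrix, TrainConfig(n_folds=4, n_lambda=40, seed=3, response_scale="log_days")
        )
        assert clock.transform.form == "exp_linear"
        assert all(v > 0 for v in report.test_predictions.values())

    def test_single_tissue_degenerates_to_plain_kfold(self):
        cfg = SyntheticConfig(
            n_samples=40, n_sites=60, n_informative=8, mean_depth=40,
            dropout_prob=0.0, tissues=("liver",), seed=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matrix, _, _ = simulate_cohort(cfg)
            matrix, _ = common_sites(matrix, 0)
            clock, report = train_clock(matrix, TrainConfig(n_folds=4, n_lambda=30))
        assert len(clock) >= 1

    def test_constant_age_rejected(self):
        pct = np.tile(np.linspace(10, 90, 8), (6, 1))
        matrix = make_matrix(pct, ages=[100.0] * 6)
        with pytest.raises(ValueError, match="degenerate"):
            train_clock(matrix, FAST)

    def test_partially_observed_rejected(self):
        pct = np.full((6, 4), 50.0)
        pct[0, 0] = np.nan
        with pytest.raises(ValueError, match="fully observed"):
            train_clock(make_matrix(pct), FAST)

    def test_deterministic_for_seed(self):
        matrix, _ = small_cohort(seed=11)
        c1, r1 = train_clock(matrix, FAST)
        c2, r2 = train_clock(matrix, FAST)
        assert c1.entries == c2.entries
        assert r1.best_lambda == r2.best_lambda


class TestEvaluateClock:
    def make_identity_clock(self, matrix):
        # weight such that one informative column reproduces age exactly is
        # overkill; instead test the metric arithmetic with a fixed clock
        return ClockDefinition(
            "toy", [ClockEntry(matrix.sites[0], 1.0)], intercept=0.0
        )

    def test_perfect_predictions(self):
        ages = [100.0, 200.0, 300.0]
        pct = np.array([[10.0], [20.0], [30.0]])
        matrix = make_matrix(pct, ages=ages)
        clock = ClockDefinition(
            "exact", [ClockEntry(matrix.sites[0], 10.0)], intercept=0.0
        )
        out = evaluate_clock(clock, matrix)
        assert out["mae_days"] == pytest.approx(0.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_mean_predictor_r2_zero(self):
        ages = [100.0, 200.0, 300.0]
        matrix = make_matrix(np.full((3, 1), 0.0), ages=ages)
        clock = ClockDefinition(
            "const", [ClockEntry(matrix.sites[0], 1.0)], intercept=200.0
        )
        out = evaluate_clock(clock, matrix)
        assert out["r2"] == pytest.approx(0.0)

    def test_toy_mae_arithmetic(self):
        ages = [100.0, 200.0, 300.0]
        pct = np.array([[11.0], [19.0], [33.0]])
        matrix = make_matrix(pct, ages=ages)
        clock = ClockDefinition(
            "toy", [ClockEntry(matrix.sites[0], 10.0)], intercept=0.0
        )
        out = evaluate_clock(clock, matrix)
        assert out["mae_days"] == pytest.approx((10 + 10 + 30) / 3)

    def test_empty_subset_rejected(self):
        matrix = make_matrix(np.full((3, 1), 50.0))
        clock = ClockDefinition("c", [ClockEntry(matrix.sites[0], 1.0)], 0.0)
        with pytest.raises(KeyError):
            evaluate_clock(clock, matrix, subset=["nope"])

    def test_no_valid_predictions_rejected(self):
        matrix = make_matrix(np.full((3, 1), 50.0))
        far_site = CpGSite("chr9", 999999)
        clock = ClockDefinition(
            "off", [ClockEntry(far_site, 1.0)], 0.0, min_site_fraction=0.9
        )
        with pytest.raises(ValueError, match="no valid predictions"):
            evaluate_clock(clock, matrix, missing_policy="global_mean_50")


def strong_signal_matrix(seed=0, n=40, p=12):
    """One column tracks age exactly; the rest are pure noise."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(50, 1000, n)
    pct = rng.uniform(20, 80, size=(n, p))
    pct[:, 0] = ages / 10.5  # 0-100 scale, perfectly informative
    tissues = ["a", "b"] * (n // 2)
    return make_matrix(pct, ages=ages, tissues=tissues)


class TestResampleClocks:
    def test_strong_signal_site_always_selected(self):
        matrix = strong_signal_matrix()
        result = resample_clocks(
            matrix, n_resamples=5, base_seed=1,
            config=TrainConfig(n_folds=4, n_lambda=30),
        )
        assert result.n_resamples == 5
        assert result.site_counts[matrix.sites[0]] == 5

    def test_never_selected_site_counts_zero(self):
        matrix = strong_signal_matrix(seed=1)
        result = resample_clocks(
            matrix, n_resamples=3, base_seed=2,
            config=TrainConfig(n_folds=4, n_lambda=30),
        )
        missing = set(matrix.sites) - set(result.site_counts)
        for site in missing:
            assert result.counts_for([site])[0] == 0

    def test_identical_base_seed_identical_result(self):
        matrix = strong_signal_matrix(seed=2)
        cfg = TrainConfig(n_folds=4, n_lambda=20)
        r1 = resample_clocks(matrix, n_resamples=3, base_seed=5, config=cfg)
        r2 = resample_clocks(matrix, n_resamples=3, base_seed=5, config=cfg)
        assert r1.site_counts == r2.site_counts

    def test_counts_bounded_by_n_resamples(self):
        matrix = strong_signal_matrix(seed=3)
        result = resample_clocks(
            matrix, n_resamples=4, base_seed=0,
            config=TrainConfig(n_folds=4, n_lambda=20),
        )
        assert all(0 < c <= 4 for c in result.site_counts.values())


class TestRobustnessStats:
    def make_result_and_clock(self, counts, weights):
        sites = [CpGSite("chr1", 100 + i) for i in range(len(counts))]
        from methage.build import RobustnessResult

        robustness = RobustnessResult(
            n_resamples=100,
            site_counts=dict(zip(sites, counts)),
            clock_summaries=[],
            base_seed=0,
        )
        clock = ClockDefinition(
            "ref",
            [ClockEntry(s, w) for s, w in zip(sites, weights)],
            intercept=0.0,
        )
        return robustness, clock, sites

    def test_enrichment_matches_exact_mwu(self):
        counts = [100, 100, 100, 1, 2, 3, 4]
        robustness, clock, sites = self.make_result_and_clock(
            counts, [1, 2, 3, 4, 5, 6, 7]
        )
        out = robustness_stats(robustness, clock, sites[:3])
        oracle = mann_whitney_u([100, 100, 100], [1, 2, 3, 4], mode="exact")
        assert out["enrichment"].p_value == pytest.approx(oracle.p_value)
        assert out["enrichment"].p_value < 0.06  # 2/35 for full separation

    def test_shuffled_counts_give_low_r2(self):
        rng = np.random.default_rng(0)
        weights = rng.normal(size=60)
        counts = rng.permutation(np.arange(60)).astype(float)
        robustness, clock, sites = self.make_result_and_clock(counts, weights)
        out = robustness_stats(robustness, clock, sites[:5])
        assert out["weight_frequency"]["r2"] < 0.1
        assert out["weight_frequency"]["p_value"] > 0.01

    def test_correlated_weights_detected(self):
        rng = np.random.default_rng(1)
        weights = np.linspace(0.1, 5, 50) * rng.choice([-1, 1], 50)
        counts = np.abs(weights) * 20 + rng.normal(0, 1, 50)
        robustness, clock, sites = self.make_result_and_clock(counts, weights)
        out = robustness_stats(robustness, clock, sites[:5])
        assert out["weight_frequency"]["r2"] > 0.8
        assert out["weight_frequency"]["p_value"] < 1e-10

    def test_constant_weights_undefined_correlation(self):
        robustness, clock, sites = self.make_result_and_clock(
            [1, 2, 3, 4, 5], [2.0] * 5
        )
        with pytest.warns(UserWarning, match="zero variance"):
            out = robustness_stats(robustness, clock, sites[:2])
        assert np.isnan(out["weight_frequency"]["r2"])

    def test_highlight_validation(self):
        robustness, clock, sites = self.make_result_and_clock(
            [1, 2, 3], [1.0, 2.0, 3.0]
        )
        with pytest.raises(ValueError, match="empty"):
            robustness_stats(robustness, clock, [])
        with pytest.raises(ValueError, match="full reference"):
            robustness_stats(robustness, clock, sites)
        with pytest.raises(ValueError, match="subset"):
            robustness_stats(robustness, clock, [CpGSite("chr9", 1)])
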