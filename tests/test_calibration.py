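import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from vocalphen import calibration

from oracles import grid_threshold


def make_samples(scores, outcomes, **extra):
    df = pd.DataFrame({"species_code": "TEST", "score": scores, "outcome": outcomes})
    for k, v in extra.items():
        df[k] = v
    return df


class TestSampler:
    @pytest.fixture()
    def records(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {"species_code": "TEST", "site_id": "S1", "day": 120,
             "segment_start": 0.0, "score": rng.uniform(0.1, 1.0, 5000)}
        )

    def test_two_range_design_fills_both_quotas(self, records):
        s = calibration.sample_validation_clips(records, 200, seed=1)
        assert len(s) == 200
        assert (s.score_range == "[0.95, 1.0]").sum() == 100
        assert (s[s.score_range == "[0.95, 1.0]"].score >= 0.95).all()

    def test_exhausted_species_returns_everything_with_warning(self):
        few = pd.DataFrame({"species_code": "X", "score": [0.2, 0.3, 0.4, 0.96, 0.5, 0.6]})
        with pytest.warns(UserWarning, match="quota"):
            s = calibration.sample_validation_clips(few, 200, seed=0)
        assert len(s) == 6

    def test_same_seed_reproduces_sample(self, records):
        a = calibration.sample_validation_clips(records, 200, seed=42)
        b = calibration.sample_validation_clips(records, 200, seed=42)
        assert a.clip_id.tolist() == b.clip_id.tolist()

    def test_nonpositive_total_rejected(self, records):
        with pytest.raises(ValueError):
            calibration.sample_validation_clips(records, 0)


class TestTruePositiveModel:
    def test_parameter_recovery_on_simulated_scores(self):
        rng = np.random.default_rng(10)
        s = rng.uniform(0, 1, 10_000)
        y = rng.binomial(1, expit(-3 + 8 * s))
        fit = calibration.fit_truepositive_model(make_samples(s, y))
        assert fit.converged
        assert abs(fit.b0 - (-3)) < 0.2
        assert abs(fit.b1 - 8) < 0.2

    def test_null_slope_when_outcome_ignores_score(self):
        rng = np.random.default_rng(11)
        s = rng.uniform(0, 1, 10_000)
        y = rng.binomial(1, 0.5, 10_000)
        fit = calibration.fit_truepositive_model(make_samples(s, y))
        assert abs(fit.b1) < 0.2

    def test_perfect_separation_is_flagged_without_finite_mle(self):
        s = np.linspace(0.1, 0.9, 40)
        y = (s > 0.5).astype(int)
        fit = calibration.fit_truepositive_model(make_samples(s, y))
        assert fit.separated
        assert not np.isfinite(fit.b1)

    def test_one_class_data_flagged_degenerate(self):
        fit = calibration.fit_truepositive_model(make_samples([0.4, 0.9], [1, 1]))
        assert fit.degenerate == "all_positive"


class TestSolveThreshold:
    def test_closed_form_ln19_over_slope(self):
        fit = calibration.CalibrationFit("X", np.array([0.0, 10.0]), ["intercept", "score"],
                                         0.0, 0.0, 200, 100, True)
        thr = calibration.solve_threshold(fit, 0.95)
        assert thr.cs_threshold == pytest.approx(np.log(19) / 10, abs=1e-12)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            b0 = rng.uniform(-8, 2)
            b1 = rng.uniform(2, 30)
            fit = calibration.CalibrationFit("X", np.array([b0, b1]),
                                             ["intercept", "score"], 0.0, 0.0, 200, 100, True)
            thr = calibration.solve_threshold(fit, 0.95)
            grid = grid_threshold(b0, b1, 0.95)
            if thr.status == "unattainable":
                assert grid is None or grid > 1.0
            else:
                assert grid is not None
                assert abs(thr.cs_threshold - grid) <= 0.001 + 1e-9

    def test_unattainable_target_thresholds_at_one(self):
        # precision never reaches 0.95 inside [0, 1] -> nothing retained
        fit = calibration.CalibrationFit("BX", np.array([-5.0, 4.0]),
                                         ["intercept", "score"], 0.0, 0.0, 200, 60, True)
        thr = calibration.solve_threshold(fit, 0.95)
        assert thr.cs_threshold == 1.0 and thr.status == "unattainable"

    def test_negative_slope_unattainable(self):
        fit = calibration.CalibrationFit("X", np.array([2.0, -1.0]),
                                         ["intercept", "score"], 0.0, 0.0, 200, 100, True)
        assert calibration.solve_threshold(fit, 0.95).status == "unattainable"

    def test_below_floor_solution_is_kept(self):
        # very accurate classifier: solution below any observed score retains all
        fit = calibration.CalibrationFit("RB", np.array([2.8, 10.0]),
                                         ["intercept", "score"], 0.0, 0.0, 200, 195, True)
        thr = calibration.solve_threshold(fit, 0.95)
        assert 0 < thr.cs_threshold < 0.1 and thr.status == "ok"


class TestFilterDetections:
    @staticmethod
    def fake_records(n_total, n_above, threshold):
        rng = np.random.default_rng(0)
        scores = np.r_[rng.uniform(0, threshold - 1e-6, n_total - n_above),
                       rng.uniform(threshold, 1.0, n_above)]
        return pd.DataFrame({"species_code": "X", "site_id": "S", "day": 120,
                             "segment_start": 0.0, "score": scores})

    @pytest.mark.parametrize("total,above,expected", [
        (152_484, 102_781, 0.67),   # scaled-down wren-like retention
        (81_819, 4_660, 0.06),      # scaled-down warbler-like retention
    ])
    def test_fraction_retained_matches_counts(self, total, above, expected):
        records = self.fake_records(total, above, 0.5)
        thr = calibration.ThresholdResult("X", 0.95, 0.5)
        _, out = calibration.filter_detections(records, thr)
        assert round(out.fraction_retained, 2) == expected
        assert out.n_retained == above

    def test_zero_threshold_is_identity_and_idempotent(self):
        records = self.fake_records(1000, 400, 0.5)
        thr = calibration.ThresholdResult("X", 0.95, 0.0)
        kept, out = calibration.filter_detections(records, thr)
        assert out.fraction_retained == 1.0 and len(kept) == len(records)
        kept2, out2 = calibration.filter_detections(kept, thr)
        assert len(kept2) == len(kept)


def clean_fit_species(study):
    """First species whose validation data yield a finite logistic MLE."""
    for sp in study.validation.species_code.unique():
        samples = study.validation[study.validation.species_code == sp]
        fit = calibration.fit_truepositive_model(samples)
        if fit.converged and not (fit.separated or fit.degenerate):
            return sp, fit
    raise AssertionError("no species with a finite calibration fit")


class TestThresholdSensitivity:
    def test_retention_and_site_counts_monotone(self, small_study):
        sp, fit = clean_fit_species(small_study)
        records = small_study.detections[small_study.detections.species_code == sp]
        table = calibration.threshold_sensitivity(records, fit, [0.5, 0.9, 0.95, 0.99])
        assert (np.diff(table.n_retained) <= 0).all()
        assert (np.diff(table.n_sites_with_labels) <= 0).all()

    def test_single_target_equals_direct_solve_and_filter(self, small_study):
        sp, fit = clean_fit_species(small_study)
        records = small_study.detections[small_study.detections.species_code == sp]
        table = calibration.threshold_sensitivity(records, fit, [0.95])
        thr = calibration.solve_threshold(fit, 0.95)
        _, direct = calibration.filter_detections(records, thr)
        assert table.n_retained.iloc[0] == direct.n_retained
        assert table.cs_threshold.iloc[0] == pytest.approx(thr.cs_threshold)

    def test_degenerate_all_max_scores_keep_site_count_constant(self):
        records = pd.DataFrame({"species_code": "X", "site_id": list("ABCD") * 5,
                                "day": 120, "segment_start": 0.0, "score": 1.0})
        fit = calibration.CalibrationFit("X", np.array([-4.0, 8.0]),
                                         ["intercept", "score"], 0.0, 0.0, 200, 100, True)
        table = calibration.threshold_sensitivity(records, fit, [0.5, 0.9, 0.95])
        assert (table.n_sites_with_labels == 4).all()


class TestDistributionShift:
    def test_duplicated_data_doubles_aic_differences(self):
        rng = np.random.default_rng(8)
        s = rng.uniform(0.1, 1, 300)
        day = rng.integers(91, 211, 300)
        strat = rng.choice(["Low", "Mid"], 300)
        y = rng.binomial(1, expit(-1 + 4 * s - 0.01 * (day - 150)))
        df = make_samples(s, y, day=day, stratum=strat)
        a1 = calibration.assess_distribution_shift(df)
        a2 = calibration.assess_distribution_shift(pd.concat([df, df], ignore_index=True))
# AIC gap minus the constant parameter-count penalty is -2 * loglik gap,
        # which doubles exactly when every row is duplicated
        g1 = a1.aic_day - a1.aic_base - 2
        g2 = a2.aic_day - a2.aic_base - 2
        assert g2 == pytest.approx(2 * g1, abs=1e-5)

    def test_missing_covariate_yields_partial_assessment(self):
        rng = np.random.default_rng(9)
        s = rng.uniform(0.1, 1, 200)
        y = rng.binomial(1, expit(-1 + 4 * s))
        out = calibration.assess_distribution_shift(make_samples(s, y))
        assert np.isnan(out.aic_day) and np.isnan(out.aic_stratum)
        assert out.notes and out.best_model == "base"
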