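"""Model fits: splits, design matrices, OLS diagnostics, selection, NN, logistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spermdfi as s
from spermdfi.errors import (
    ClassBalanceError,
    ConfigurationError,
    RankError,
    SchemaError,
)
from spermdfi.modeling import (
    LinearModelSpec,
    NNConfig,
    candidate_terms,
    centers_from_table,
    fit_linear,
    fit_logistic,
    fit_nn,
    forward_select,
    intercept_term,
    main_term,
    product_term,
    split_data,
)
from spermdfi.synthetic import TABLE1_CENTERS

from conftest import make_table


class TestSplitData:
    @pytest.mark.parametrize("n,fractions,expected", [
        (1000, (0.65, 0.10, 0.25), (650, 100, 250)),
        (1056, (0.65, 0.10, 0.25), (687, 105, 264)),
        (100, (0.8, 0.2, 0.0), (80, 20, 0)),
    ])
    def test_sizes_floor_with_train_first_remainders(self, n, fractions, expected):
        split = split_data(n, fractions, seed=0)
        counts = split.counts()
        assert (counts["train"], counts["validation"], counts["test"]) == expected

    def test_deterministic_per_seed(self):
        a = split_data(500, seed=7)
        b = split_data(500, seed=7)
        c = split_data(500, seed=8)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert (a.labels != c.labels).any()

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            split_data(100, (0.7, -0.1, 0.4), seed=0)
        with pytest.raises(ConfigurationError):
            split_data(100, (0.5, 0.1, 0.1), seed=0)


class TestDesignMatrix:
    def test_centering_identity_at_center_point(self):
        table = make_table({f: [c] for f, c in TABLE1_CENTERS.items()})
        X = s.build_design_matrix(table, s.table1_model())
        # intercept and three uncentered mains are nonzero, all else vanishes
        nonzero = np.flatnonzero(np.abs(X[0]) > 1e-9)
        assert set(nonzero) == {0, 1, 2, 3}

    def test_candidate_set_has_28_columns(self):
        table = make_table({f: np.linspace(1, 2, 5) for f in s.FEATURES})
        cands = candidate_terms(centers_from_table(table))
        assert len(cands) == 28
        X = np.column_stack([t.column(table) for t in cands])
        assert X.shape == (5, 28)

    def test_table1_spec_has_14_columns(self):
        table = make_table({f: np.linspace(1, 2, 4) for f in s.FEATURES})
        assert s.build_design_matrix(table, s.table1_model()).shape == (4, 14)

    def test_missing_feature_raises_schema_error(self):
        table = make_table({f: [1.0, 2.0] for f in s.FEATURES}).drop(columns=["VA"])
        with pytest.raises(SchemaError, match="VA"):
            s.build_design_matrix(table, s.table1_model())


class TestFitLinear:
    def test_zero_noise_recovery_to_six_digits(self):
        cfg = s.SyntheticConfig(n_cells=1056, seed=1, noise_sd=0.0,
                                donor_shift_sd=0.0)
        table, _ = s.generate_feature_table(cfg)
        fit = fit_linear(table, LinearModelSpec(list(s.table1_model().terms)))
        np.testing.assert_allclose(fit.estimates, s.table1_model().estimates,
                                   rtol=1e-6)

    def test_orthonormal_predictors_have_unit_vif(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        table = make_table({"C": x1, "HW": x2})
        spec = LinearModelSpec([intercept_term(), main_term("C"), main_term("HW")])
        rng = np.random.default_rng(0)
        fit = fit_linear(table, spec, response=x1 + rng.normal(0, 1, n))
        np.testing.assert_allclose(fit.vifs[1:], 1.0, atol=1e-12)

    def test_duplicated_column_raises_rank_error(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        table = make_table({"C": x, "HW": x})
        spec = LinearModelSpec([intercept_term(), main_term("C"), main_term("HW")])
        with pytest.raises(RankError, match="HW|C"):
            fit_linear(table, spec, response=x)

    def test_t_ratios_and_pvalues_consistent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        y = 1 + 0.5 * x + rng.normal(0, 1, 80)
        fit = fit_linear(make_table({"C": x}),
                         LinearModelSpec([intercept_term(), main_term("C")]),
                         response=y)
        np.testing.assert_allclose(fit.t_ratios, fit.estimates / fit.std_errors)
        expect_p = 2 * stats.t.sf(np.abs(fit.t_ratios), fit.dof)
        np.testing.assert_allclose(fit.p_values, expect_p)
        assert ((fit.p_values >= 0) & (fit.p_values <= 1)).all()

    def test_confidence_interval_coverage_is_nominal(self):
        # 95% t-intervals for a known slope cover it ~95% of the time
        rng = np.random.default_rng(7)
        spec = LinearModelSpec([intercept_term(), main_term("C")])
        cover = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(0, 1, 60)
            y = 2 + 1.5 * x + rng.normal(0, 0.8, 60)
            fit = fit_linear(make_table({"C": x}), spec, response=y)
            tcrit = stats.t.ppf(0.975, fit.dof)
            lo = fit.estimates[1] - tcrit * fit.std_errors[1]
            hi = fit.estimates[1] + tcrit * fit.std_errors[1]
            cover += lo <= 1.5 <= hi
        assert cover / reps == pytest.approx(0.95, abs=0.02)


class TestForwardSelect:
    @staticmethod
    def _truth_and_table(seed):
        cfg = s.SyntheticConfig(n_cells=400, seed=100 + seed, noise_sd=0.0,
                                donor_shift_sd=0.0)
        table, _ = s.generate_feature_table(cfg)
        centers = centers_from_table(table)
        truth = LinearModelSpec(
            [intercept_term(), main_term("AA"),
             product_term("C", centers["C"], "C", centers["C"]),
             product_term("L", centers["L"], "VA", centers["VA"])],
            np.array([0.0, -0.06, -5.16, -0.3]))
        y = truth.predict(table)
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0, 0.02 * np.std(y), len(y))
        return table, centers, truth, y

    def test_recovers_true_terms_at_high_snr(self):
        hits = 0
        for seed in range(10):
            table, centers, truth, y = self._truth_and_table(seed)
            sel = forward_select(table, candidate_terms(centers), seed=seed,
                                 response=y)
            hits += set(sel.term_names) == set(truth.term_names)
        assert hits >= 9

    def test_pure_noise_selects_intercept_only_in_most_seeds(self):
        sizes = []
        for seed in range(10):
            cfg = s.SyntheticConfig(n_cells=300, seed=seed)
            table, _ = s.generate_feature_table(cfg)
            rng = np.random.default_rng(seed)
            y = rng.normal(size=len(table))
            sel = forward_select(table, candidate_terms(centers_from_table(table)),
                                 seed=seed, response=y)
            sizes.append(len(sel.terms))
        assert sum(n == 1 for n in sizes) >= 5  # intercept-only in most seeds
        assert max(sizes) <= 3                  # never more than 2 noise terms

    def test_deterministic_given_seed(self):
        table, centers, _, y = self._truth_and_table(0)
        a = forward_select(table, candidate_terms(centers), seed=3, response=y)
        b = forward_select(table, candidate_terms(centers), seed=3, response=y)
        assert a.term_names == b.term_names


class TestFitNN:
    def test_noiseless_linear_map_is_learned(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 6))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 1.5, -0.7]) + 0.3
        table = make_table({f: X[:, i] for i, f in enumerate(s.FEATURES)})
        split = split_data(500, seed=0)
        reg = fit_nn(table, split, NNConfig(seed=0), response=y)
        r = s.pearson_r(y[split.test], reg.predict(table)[split.test])
        assert r >= 0.99

    def test_learns_nonlinearity_where_linear_fit_fails(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-4, 4, 500)
        y = np.sin(3 * x) + rng.normal(0, 0.05, 500)
        table = make_table({"C": x})
        split = split_data(500, seed=1)
        reg = fit_nn(table, split, NNConfig(seed=1), features=["C"], response=y)
        r_nn = s.pearson_r(y[split.test], reg.predict(table)[split.test])
        slope = np.polyfit(x[split.train], y[split.train], 1)
        r_lin = s.pearson_r(y[split.test], np.polyval(slope, x[split.test]))
        assert r_nn >= 0.95
        assert abs(r_lin) < 0.5  # the linear fit cannot track sin(3x)

    def test_constant_response_flagged(self):
        table = make_table({f: np.random.default_rng(0).normal(size=50)
                            for f in s.FEATURES})
        split = split_data(50, seed=0)
        reg = fit_nn(table, split, NNConfig(seed=0, max_epochs=5),
                     response=np.full(50, 1.3))
        assert reg.degenerate_response
        assert np.ptp(reg.predict(table)) < 1e-6

    def test_returned_weights_minimize_validation_loss(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 6))
        y = np.tanh(X[:, 0]) + 0.2 * X[:, 1] ** 2 + rng.normal(0, 0.2, 300)
        table = make_table({f: X[:, i] for i, f in enumerate(s.FEATURES)})
        split = split_data(300, seed=4)
        reg = fit_nn(table, split, NNConfig(seed=4), response=y)
        val = table[split.validation]
        final = float(np.mean((reg.predict(val) - y[split.validation]) ** 2))
        best_scaled = min(reg.history["validation"]) * reg.y_sd ** 2
        assert final == pytest.approx(best_scaled, rel=1e-6)

    def test_empty_validation_rejected(self):
        table = make_table({f: np.arange(10.0) for f in s.FEATURES})
        split = split_data(10, (0.8, 0.2, 0.0), seed=0)
        split.labels[split.labels == "validation"] = "train"
        with pytest.raises(ConfigurationError):
            fit_nn(table, split, NNConfig(seed=0), response=np.arange(10.0))


class TestFitLogistic:
    def test_positive_label_fraction_matches_threshold(self):
        cfg = s.SyntheticConfig(n_cells=1000, seed=5)
        table, _ = s.generate_feature_table(cfg)
        split = split_data(table, seed=5)
        fit = fit_logistic(table, split, threshold_percentile=80, seed=5)
        labels = fit.true_labels(table)
        frac = labels[split.train].mean()
        assert frac == pytest.approx(0.20, abs=0.01)

    def test_separable_classes_classified_perfectly(self):
        rng = np.random.default_rng(0)
        n = 400
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 0.3, size=(n, 6)) + 3.0 * y[:, None]
        table = make_table({f: X[:, i] for i, f in enumerate(s.FEATURES)})
        # craft a response whose rank split reproduces the classes
        response = y * 2.0 + rng.normal(0, 0.1, n)
        split = split_data(n, seed=0)
        fit = fit_logistic(table, split, threshold_percentile=50, seed=0,
                           response=response)
        pred = fit.predict_label(table)
        truth = fit.true_labels(table, response=response)
        acc = (pred[split.test] == truth[split.test]).mean()
        assert acc >= 0.99

    def test_coefficient_recovery_within_three_se(self):
        rng = np.random.default_rng(8)
        n = 5000
        X = rng.normal(size=(n, 6))
        beta = np.array([0.8, -0.5, 0.0, 0.3, -0.2, 0.6])
        p = 1 / (1 + np.exp(-(0.2 + X @ beta)))
        labels = rng.binomial(1, p)
        table = make_table({f: X[:, i] for i, f in enumerate(s.FEATURES)})
        # response whose median split equals the drawn labels
        response = labels + rng.uniform(-0.4, 0.4, n)
        split = split_data(n, (0.98, 0.01, 0.01), seed=8)
        fit = fit_logistic(table, split, threshold_percentile=50, seed=8,
                           response=response)
        # refit labels are exactly `labels` on train, so compare coefficients
        for f, b_true in zip(s.FEATURES, beta):
            se = fit.std_errors[f]
            assert abs(fit.coefficients[f] - b_true) <= 3 * se

    def test_single_class_training_rejected(self):
        cfg = s.SyntheticConfig(n_cells=100, seed=2)
        table, _ = s.generate_feature_table(cfg)
        split = split_data(table, seed=2)
        with pytest.raises(ClassBalanceError):
            fit_logistic(table, split, threshold_percentile=100, seed=2)
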