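"""Predictor construction and per-cell rERP fitting."""

import logging

import numpy as np
import pandas as pd
import pytest

from trialdyn import (N400_WINDOW, SEGMENT_WINDOW, WindowSpec, build_predictors,
                      fit_by_condition, fit_cell, fit_rerp, grand_average,
                      summarize_coefficients)
from trialdyn.errors import (AlignmentError, DegenerateInputError, DomainError,
                             SingularDesignError)
from trialdyn.rerp import PredictorTable

from conftest import make_epochs


def _constant_trial_epochs(levels, electrodes=("Pz",), n_samples=20,
                           subjects=None):
    """Each trial is a constant waveform at the given level."""
    levels = np.asarray(levels, dtype=float)
    v = np.tile(levels[:, None, None], (1, len(electrodes), n_samples))
    times = np.linspace(0, 1200, n_samples)
    return make_epochs(v, electrodes=list(electrodes), times=times,
                       subjects=subjects)


class TestBuildPredictors:
    def test_hand_computed_z_scores(self):
        ep = _constant_trial_epochs([-4.0, 0.0, 4.0])
        table = build_predictors(ep, WindowSpec("N400", 300, 500),
                                 WindowSpec("Segment", 0, 1200))
        # raw averages (-4, 0, 4), sample sd 4 -> z = (-1, 0, 1) -> inverted
        np.testing.assert_allclose(table.n400[:, 0], [1.0, 0.0, -1.0], atol=1e-12)
        np.testing.assert_allclose(table.segment[:, 0], [1.0, 0.0, -1.0], atol=1e-12)
        meta = table.standardization
        assert set(meta["predictor"]) == {"N400", "Segment"}
        np.testing.assert_allclose(meta["sd_uv"], 4.0)

    def test_mean_zero_sd_one_contract(self, random_epochs):
        table = build_predictors(random_epochs)
        for arr in (table.n400, table.segment):
            np.testing.assert_allclose(arr.mean(axis=0), 0.0, atol=1e-9)
            np.testing.assert_allclose(arr.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_per_subject_scope_contract(self, random_epochs):
        table = build_predictors(random_epochs, scope="per_subject")
        subj = random_epochs.trials["subject"].to_numpy()
        for s in np.unique(subj):
            m = subj == s
            np.testing.assert_allclose(table.n400[m].mean(axis=0), 0.0, atol=1e-9)
            np.testing.assert_allclose(table.n400[m].std(axis=0, ddof=1), 1.0,
                                       atol=1e-9)

    def test_inversion_most_negative_raw_gets_largest_predictor(self, random_epochs):
        from trialdyn import window_average
        table = build_predictors(random_epochs)
        for e, el in enumerate(random_epochs.electrodes):
            raw = window_average(random_epochs, N400_WINDOW, el)
            assert np.argmin(raw) == np.argmax(table.n400[:, e])

    def test_constant_window_average_rejected(self):
        ep = _constant_trial_epochs([2.0, 2.0, 2.0])
        with pytest.raises(DegenerateInputError, match="zero"):
            build_predictors(ep, WindowSpec("N400", 300, 500),
                             WindowSpec("Segment", 0, 1200))


class TestFitCell:
    def test_intercept_only_is_mean(self):
        beta, se = fit_cell([1.0, 2.0, 3.0])
        assert beta[0] == pytest.approx(2.0)
        assert se[0] == pytest.approx(1.0 / np.sqrt(3))  # sd 1 / sqrt(n)

    def test_two_point_closed_form(self):
        beta, se = fit_cell([0.0, 4.0])
        assert beta[0] == pytest.approx(2.0)
        assert se[0] == pytest.approx(2.0)  # sigma^2 = 8, se = sqrt(8/2)

    def test_matches_normal_equations(self, rng):
        for _ in range(20):
            X = rng.normal(size=(50, 2))
            y = rng.normal(size=50)
            beta, se = fit_cell(y, X)
            D = np.column_stack([np.ones(50), X])
            expected = np.linalg.solve(D.T @ D, D.T @ y)
            np.testing.assert_allclose(beta, expected, atol=1e-8)
            resid = y - D @ expected
            sigma2 = (resid ** 2).sum() / (50 - 3)
            exp_se = np.sqrt(np.diag(sigma2 * np.linalg.inv(D.T @ D)))
            np.testing.assert_allclose(se, exp_se, atol=1e-8)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(40, 2))
        y = 1.0 + X @ [0.5, -2.0] + rng.normal(size=40)
        beta, se = fit_cell(y, X)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-10)
        np.testing.assert_allclose(se, ref.bse, atol=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(SingularDesignError):
            fit_cell(rng.normal(size=20), np.column_stack([x, 2 * x]))

    def test_too_few_trials_rejected(self):
        with pytest.raises(DomainError):
            fit_cell([1.0, 2.0], np.ones((2, 2)))


class TestFitRerp:
    def test_intercept_only_equals_grand_average(self, small_biphasic):
        epochs, _, _ = small_biphasic
        coeffs = fit_rerp(epochs, predictors=None)
        avg_beta0 = coeffs.beta[:, :, :, 0].mean(axis=0)
        erp = grand_average(epochs, group_by=())
        d = erp.data
        for e, el in enumerate(epochs.electrodes):
            ref = d[d["electrode"] == el].sort_values("time_ms")["mean_uv"].to_numpy()
            assert np.abs(avg_beta0[e] - ref).max() < 1e-10

    def test_intercepts_are_per_subject_means(self, random_epochs):
        coeffs = fit_rerp(random_epochs, predictors=None)
        for si, s in enumerate(coeffs.subjects):
            m = (random_epochs.trials["subject"] == s).to_numpy()
            np.testing.assert_allclose(coeffs.beta[si, :, :, 0],
                                       random_epochs.voltages[m].mean(axis=0),
                                       atol=1e-12)

    def test_zero_predictors_raise_singular(self, random_epochs):
        n, e = random_epochs.n_trials, len(random_epochs.electrodes)
        table = PredictorTable(n400=np.zeros((n, e)), segment=np.zeros((n, e)),
                               electrodes=list(random_epochs.electrodes),
                               standardization=pd.DataFrame())
        with pytest.raises(SingularDesignError):
            fit_rerp(random_epochs, table)

    def test_small_subjects_skipped_with_warning(self, caplog):
        subjects = ["S1"] * 6 + ["S2"] * 2
        ep = make_epochs(np.random.default_rng(0).normal(size=(8, 1, 10)),
                         subjects=subjects, electrodes=["Pz"])
        with caplog.at_level(logging.WARNING, logger="trialdyn.rerp"):
            coeffs = fit_rerp(ep, predictors=None)
        assert coeffs.subjects == ["S1"]
        assert "skipped" in caplog.text

    def test_all_subjects_too_small_rejected(self):
        ep = make_epochs(np.zeros((2, 1, 5)), subjects=["S1", "S2"])
        with pytest.raises(DomainError):
            fit_rerp(ep, predictors=None)

    def test_misaligned_predictor_table_rejected(self, random_epochs):
        table = build_predictors(random_epochs)
        with pytest.raises(AlignmentError):
            fit_rerp(random_epochs.subset(np.arange(10)), table)

    def test_coefficient_frame_round_trip(self, small_biphasic):
        from trialdyn.rerp import CoefficientSet
        epochs, _, _ = small_biphasic
        coeffs = fit_rerp(epochs, build_predictors(epochs))
        back = CoefficientSet.from_frame(coeffs.to_frame())
        np.testing.assert_allclose(back.beta, coeffs.beta, atol=1e-12)
        np.testing.assert_allclose(back.se_ols, coeffs.se_ols, atol=1e-12)
        assert back.terms == coeffs.terms


class TestSummaries:
    def test_single_subject_ribbon_zero(self, rng):
        ep = make_epochs(rng.normal(size=(6, 1, 10)), electrodes=["Pz"])
        out = summarize_coefficients(fit_rerp(ep, predictors=None))
        np.testing.assert_allclose(out.data["se_uv"], 0.0)

    def test_add_intercept_shifts_by_intercept_trace(self, small_biphasic):
        epochs, _, _ = small_biphasic
        coeffs = fit_rerp(epochs, build_predictors(epochs))
        plain = summarize_coefficients(coeffs, add_intercept=False).data
        shifted = summarize_coefficients(coeffs, add_intercept=True).data
        b0 = plain[plain["term"] == "intercept"]
        for term in ("N400", "Segment"):
            a = plain[plain["term"] == term].sort_values(["electrode", "time_ms"])
            b = shifted[shifted["term"] == term].sort_values(["electrode", "time_ms"])
            np.testing.assert_allclose(
                b["mean_uv"].to_numpy() - a["mean_uv"].to_numpy(),
                b0.sort_values(["electrode", "time_ms"])["mean_uv"].to_numpy(),
                atol=1e-10)

    def test_across_subject_mean_matches_loop(self, small_biphasic):
        epochs, _, _ = small_biphasic
        coeffs = fit_rerp(epochs, build_predictors(epochs))
        out = summarize_coefficients(coeffs).data
        k = coeffs.terms.index("N400")
        cell = out[(out["term"] == "N400") & (out["electrode"] == "Pz")] \
            .sort_values("time_ms")["mean_uv"].to_numpy()
        e = coeffs.electrodes.index("Pz")
        manual = np.mean([coeffs.beta[s, e, :, k]
                          for s in range(len(coeffs.subjects))], axis=0)
        np.testing.assert_allclose(cell, manual, atol=1e-12)

    def test_ols_ribbon_option(self, small_biphasic):
        epochs, _, _ = small_biphasic
        coeffs = fit_rerp(epochs, build_predictors(epochs))
        subj = summarize_coefficients(coeffs, ribbon="subjects").data
        ols = summarize_coefficients(coeffs, ribbon="ols").data
        assert not np.allclose(subj["se_uv"], ols["se_uv"])

    def test_segment_coefficient_magnitude_grows_over_epoch(self, small_biphasic):
        # directed drifts: the Segment term's pull increases across the epoch
        from scipy.stats import spearmanr
        epochs, _, _ = small_biphasic
        coeffs = fit_rerp(epochs, build_predictors(epochs))
        out = summarize_coefficients(coeffs).data
        tr = out[(out["term"] == "Segment") & (out["electrode"] == "Pz") &
                 (out["time_ms"] >= 0)].sort_values("time_ms")
        rho = spearmanr(tr["time_ms"], tr["mean_uv"].abs()).statistic
        assert rho > 0


class TestFitByCondition:
    def test_single_condition_equals_full_fit(self, rng):
        ep = make_epochs(rng.normal(size=(12, 1, 16)), electrodes=["Pz"],
                         times=np.linspace(0, 1200, 16))
        full = fit_rerp(ep, build_predictors(ep))
        only = fit_by_condition(ep, "A")
        np.testing.assert_allclose(only.beta, full.beta, atol=1e-10)

    def test_intercepts_equal_per_condition_means(self, small_biphasic):
        # per-subject standardization zeroes each subject's predictor means,
        # so the intercept is exactly that subject's condition average
        epochs, _, _ = small_biphasic
        cond = epochs.conditions[0]
        coeffs = fit_by_condition(epochs, cond, scope="per_subject")
        m = (epochs.trials["condition"] == cond).to_numpy()
        sub = epochs.subset(np.flatnonzero(m))
        for si, s in enumerate(coeffs.subjects):
            sm = (sub.trials["subject"] == s).to_numpy()
            np.testing.assert_allclose(coeffs.beta[si, :, :, 0],
                                       sub.voltages[sm].mean(axis=0), atol=1e-9)

    def test_unknown_condition_rejected(self, small_biphasic):
        epochs, _, _ = small_biphasic
        with pytest.raises(DomainError):
            fit_by_condition(epochs, "Nope")
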