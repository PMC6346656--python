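"""Outcome transform, screening, AICc all-subset selection, group tests."""

import math

import numpy as np
import pandas as pd
import pytest

import neurocog.association as assoc
from neurocog.errors import (
    EmptyGroupError,
    EnumerationBudgetError,
    TableValidationError,
)
from neurocog.synthetic import CohortConfig, generate_marker_table, generate_outcomes


def _cohort_table(n=111, seed=0, **kwargs):
    cfg = CohortConfig(n_subjects=n, seed=seed, **kwargs)
    mt = generate_marker_table(cfg)
    out, truth = generate_outcomes(cfg, mt)
    return assoc.make_cohort_table(mt, out), truth


# ---------------------------------------------------------------------------
# outcome transform


def test_log_z_transform_moments_and_monotonicity():
    mmse = np.array([20, 24, 30, 18, 27, 22])
    z = assoc.transform_outcome(mmse)
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.std() == pytest.approx(1.0, abs=1e-9)
    assert (np.argsort(z) == np.argsort(mmse)).all()


def test_constant_mmse_flagged():
    with pytest.warns(UserWarning):
        z = assoc.transform_outcome(np.full(10, 25))
    assert (z == 0).all()


def test_mmse_below_one_rejected():
    with pytest.raises(TableValidationError):
        assoc.transform_outcome(np.array([0, 25, 30]))


def test_cohort_table_columns_standardized():
    table, _ = _cohort_table(n=40, seed=1)
    for col in table.attrs["markers"]:
        assert table[col].mean() == pytest.approx(0.0, abs=1e-9)
        assert table[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
    assert table["group"].dtype == bool


# ---------------------------------------------------------------------------
# univariate screening


def test_single_regressor_f_matches_closed_form(rng):
    n = 102
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    mmse = np.clip(np.round(24 + 3 * y), 1, 30)
    df = pd.DataFrame({"subject_id": range(n), "m": x})
    table = df.copy()
    table["m"] = assoc.zscore(x)
    table["mmse_logz"] = assoc.transform_outcome(mmse)
    r = np.corrcoef(table["m"], table["mmse_logz"])[0, 1]
    fit = assoc.fit_regression(table, ("m",), covariates=())
    f_closed = r**2 * (n - 2) / (1 - r**2)
    assert float(fit.tvalues["m"]) ** 2 == pytest.approx(f_closed, rel=1e-9)


def test_marker_identical_to_outcome_gives_unit_r2():
    table, _ = _cohort_table(n=40, seed=2)
    table["clone"] = table["mmse_logz"]
    fit = assoc.fit_regression(table, ("clone",), covariates=())
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    assert float(fit.pvalues["clone"]) < 1e-30


def test_type_one_error_rate_near_alpha(rng):
    # planted-null simulation: marker independent of outcome, covariates in
    n, reps, alpha = 60, 1000, 0.05
    hits = 0
    for _ in range(reps):
        df = pd.DataFrame(
            {
                "subject_id": range(n),
                "m": rng.normal(size=n),
                "age": rng.normal(size=n),
                "sex": rng.integers(0, 2, n),
                "education": rng.normal(size=n),
                "mmse_logz": rng.normal(size=n),
            }
        )
        fit = assoc.fit_regression(df, ("m",))
        hits += float(fit.pvalues["m"]) < alpha
    assert hits / reps == pytest.approx(alpha, abs=0.02)


def test_screen_reports_every_marker():
    table, _ = _cohort_table(n=50, seed=3)
    screen = assoc.univariate_screen(table)
    assert len(screen) == 25
    assert {"slope", "F", "p", "r_unadjusted"} <= set(screen.columns)


# ---------------------------------------------------------------------------
# intercorrelation


def test_intercorrelation_symmetric_unit_diagonal():
    table, _ = _cohort_table(n=60, seed=4)
    corr, sig = assoc.intercorrelation(table)
    np.testing.assert_array_equal(corr.to_numpy(), corr.to_numpy().T)
    np.testing.assert_allclose(np.diag(corr), 1.0)
    assert not np.diag(sig).any()


def test_duplicated_column_perfectly_correlated():
    table, _ = _cohort_table(n=30, seed=5)
    table["dup"] = table["iaf"]
    corr, sig = assoc.intercorrelation(table, markers=["iaf", "dup", "ami"])
    assert corr.loc["iaf", "dup"] == pytest.approx(1.0)
    assert sig.loc["iaf", "dup"]


def test_independent_columns_uncorrelated_at_large_n(rng):
    n = 5000
    df = pd.DataFrame(
        {
            "subject_id": range(n),
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
            "c": rng.normal(size=n),
        }
    )
    corr, sig = assoc.intercorrelation(df, markers=["a", "b", "c"])
    off = corr.to_numpy()[~np.eye(3, dtype=bool)]
    assert np.abs(off).max() < 0.05


# ---------------------------------------------------------------------------
# regression and AICc


def test_planted_coefficients_recovered_without_noise(rng):
    n = 64
    q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
    x = q * math.sqrt(n)  # orthonormal-ish standardized design
    beta = np.array([0.5, -0.3, 0.2])
    y = x @ beta
    df = pd.DataFrame(x, columns=["m1", "m2", "m3"])
    df["subject_id"] = range(n)
    df["mmse_logz"] = y
    fit = assoc.fit_regression(df, ("m1", "m2", "m3"), covariates=())
    np.testing.assert_allclose(
        fit.params[["m1", "m2", "m3"]].to_numpy(), beta, atol=1e-10
    )
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)


def test_empty_subset_equals_covariate_only_model():
    table, _ = _cohort_table(n=60, seed=6)
    fit = assoc.fit_regression(table, ())
    direct = assoc.fit_regression(table, (), covariates=assoc.COVARIATES)
    assert fit.r2 == pytest.approx(direct.r2, abs=1e-12)
    assert 0 <= fit.r2 <= 1


def test_aicc_against_independent_formula_oracle():
    def oracle(n, rss, kp):  # independently coded
        return n * math.log(rss / n) + 2 * kp + (2 * kp * (kp + 1)) / (n - kp - 1)

    assert assoc.aicc_from_rss(20, 5.0, 3) == pytest.approx(oracle(20, 5.0, 3), abs=1e-12)
    assert assoc.aicc_from_rss(111, 42.0, 10) == pytest.approx(
        oracle(111, 42.0, 10), abs=1e-12
    )


@pytest.mark.parametrize("n,kp", [(20, 3), (50, 5), (500, 5), (5000, 5)])
def test_aicc_dominates_aic_and_converges(n, kp):
    rss = 10.0
    aic = n * math.log(rss / n) + 2 * kp
    aicc = assoc.aicc_from_rss(n, rss, kp)
    assert aicc >= aic
    if n >= 5000:
        assert aicc - aic < 0.02


# ---------------------------------------------------------------------------
# all-subset selection


def test_planted_subset_recovered_at_zero_noise():
    table, truth = _cohort_table(n=111, seed=10, population_r2=None, noise_sd=0.0)
    sel = assoc.all_subset_select(table, max_size=6)
    assert sorted(sel.best.subset) == sorted(truth.planted_subset)
    assert len(sel.ranked) == 10
    aiccs = [a for _, a, _ in sel.ranked]
    assert aiccs == sorted(aiccs)


def test_duplicate_regressor_tie_broken_lexicographically():
    table, _ = _cohort_table(
        n=80, seed=11, population_r2=0.9,
        effect_beta={"vol_hippocampus": 1.0},
    )
    table["aa_clone"] = table["vol_hippocampus"]
    sel = assoc.all_subset_select(
        table, candidates=["aa_clone", "vol_hippocampus"], max_size=2
    )
    assert sel.best.subset == ("aa_clone",)  # lexicographic winner, size 1


def test_null_candidates_prefer_covariate_only_model(rng):
    # With a couple of pure-noise candidates the AICc penalty should favor
    # the covariate-only model in most replicates.
    wins = 0
    reps = 20
    for rep in range(reps):
        n = 111
        df = pd.DataFrame(
            {
                "subject_id": range(n),
                "u1": rng.normal(size=n),
                "u2": rng.normal(size=n),
                "age": rng.normal(size=n),
                "sex": rng.integers(0, 2, n),
                "education": rng.normal(size=n),
                "mmse_logz": rng.normal(size=n),
            }
        )
        sel = assoc.all_subset_select(df, candidates=["u1", "u2"], max_size=2)
        wins += sel.best.subset == ()
    assert wins > reps / 2


def test_enumeration_budget_enforced():
    table, _ = _cohort_table(n=40, seed=12)
    with pytest.raises(EnumerationBudgetError):
        assoc.all_subset_select(table, max_size=8, fit_budget=1000)


def test_selection_improves_with_sample_size_and_snr():
    def rate(n, r2, reps=3):
        hits = 0
        for rep in range(reps):
            table, truth = _cohort_table(
                n=n, seed=1000 + rep,
                population_r2=r2,
                effect_beta={"vol_hippocampus": 0.5, "power_theta": -0.5},
            )
            sel = assoc.all_subset_select(
                table,
                candidates=["vol_hippocampus", "power_theta", "iaf", "ami",
                            "vol_frontal", "thk_occipital"],
                max_size=2,
            )
            hits += sorted(sel.best.subset) == sorted(truth.planted_subset)
        return hits / reps

    assert rate(200, 0.9) >= rate(40, 0.25)
    assert rate(200, 0.9) == 1.0


# ---------------------------------------------------------------------------
# partial regression data


def test_partial_residual_slope_equals_joint_coefficient():
    table, truth = _cohort_table(n=80, seed=13)
    fit = assoc.fit_regression(table, truth.planted_subset)
    pairs = assoc.partial_regression_data(table, fit)
    for m, (x_res, y_res) in pairs.items():
        slope = np.dot(x_res, y_res) / np.dot(x_res, x_res)
        assert slope == pytest.approx(float(fit.params[m]), abs=1e-10)


def test_single_regressor_partial_plot_is_plain_scatter(rng):
    n = 50
    df = pd.DataFrame({"subject_id": range(n), "m": assoc.zscore(rng.normal(size=n))})
    df["mmse_logz"] = 0.6 * df["m"] + 0.1 * rng.normal(size=n)
    fit = assoc.fit_regression(df, ("m",), covariates=())
    (x_res, y_res) = assoc.partial_regression_data(df, fit, covariates=())["m"]
    # only the intercept is partialled out: centered original data
    np.testing.assert_allclose(x_res, df["m"] - df["m"].mean(), atol=1e-10)
    np.testing.assert_allclose(y_res, df["mmse_logz"] - df["mmse_logz"].mean(), atol=1e-10)


# ---------------------------------------------------------------------------
# group tests


def test_cdr_association_matches_continuity_corrected_chi_square():
    stat, p = assoc.chi2_yates(np.array([[47, 16], [26, 22]]))
    assert round(stat, 2) == 4.19
    assert p == pytest.approx(0.041, abs=0.0005)


def test_proportional_table_has_zero_statistic():
    stat, _ = assoc.chi2_yates(np.array([[20, 40], [10, 20]]))
    assert stat == pytest.approx(0.0, abs=1e-12)


def test_identical_group_distributions_not_significant(rng):
    n = 200
    base = rng.normal(size=n // 2)
    df = pd.DataFrame(
        {
            "subject_id": range(n),
            "age": np.concatenate([base, base]),
            "education": np.concatenate([base, base]),
            "sex": np.tile([0, 1], n // 2),
            "cdr": np.tile([0.5, 1.0], n // 2),
            "group": np.repeat([True, False], n // 2),
        }
    )
    res = df.pipe(assoc.group_tests)
    assert res.loc["age", "p"] > 0.9
    assert res.loc["education", "p"] > 0.9


def test_empty_group_rejected():
    df = pd.DataFrame(
        {"subject_id": [1, 2], "age": [70, 71], "education": [10, 12],
         "sex": [0, 1], "cdr": [0.5, 1.0], "group": [True, True]}
    )
    with pytest.raises(EmptyGroupError):
        assoc.group_tests(df)
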