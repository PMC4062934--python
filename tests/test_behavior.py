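"""Learning models, nested comparisons, Latin-square layouts, learning curves."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from petalpol import behavior as bh
from petalpol import synthetic_scene as ss

from helpers import check_rearrangement_constraints


# ---------------------------------------------------------------------------
# Latin-square layouts


def test_order_4_latin_square_enumeration():
    squares = bh.all_latin_squares_4()
    assert len(squares) == 576  # known count for order 4
    as_tuples = {tuple(sq.ravel()) for sq in squares}
    assert len(as_tuples) == 576


def test_trial_layout_validation():
    with pytest.raises(ValueError, match="row and column"):
        bh.TrialLayout(grid=np.tile([1, 2, 3, 4], (4, 1)))
    layout = bh.random_layout(seed=0)
    assert layout.target_grid is not None
    # each condition fields exactly 4 targets
    counts = pd.Series(layout.grid.ravel()).value_counts()
    assert (counts == 4).all()


def test_shuffle_layout_satisfies_all_constraints():
    layout = bh.random_layout(seed=1)
    for seed in range(200):
        new = bh.shuffle_layout(layout, seed=seed)
        checks = check_rearrangement_constraints(layout, new)
        assert all(checks.values()), checks
        layout = new


def test_shuffle_layout_is_not_constant():
    base = bh.random_layout(seed=2)
    grids = {tuple(bh.shuffle_layout(base, seed=s).grid.ravel()) for s in range(30)}
    assert len(grids) > 1


# ---------------------------------------------------------------------------
# Choice tables


def test_choice_table_validation():
    good = ss.simulate_choices(n_bees=2, n_trials=5, seed=0)
    bh.validate_choice_table(good)
    bad = good.copy()
    bad.loc[3, "trial"] = 99
    with pytest.raises(ValueError, match="contiguous"):
        bh.validate_choice_table(bad)
    with pytest.raises(ValueError, match="missing columns"):
        bh.validate_choice_table(good.drop(columns=["condition"]))


def test_choice_csv_round_trip(tmp_path):
    table = ss.simulate_choices(n_bees=3, n_trials=10, seed=1)
    path = tmp_path / "choices.csv"
    bh.write_choices(path, table)
    back = bh.read_choices(path)
    pd.testing.assert_frame_equal(back, table)


def test_intensity_of_condition_mapping():
    conditions = pd.Series([1, 2, 3, 4])
    assert list(bh.intensity_of_condition(conditions)) == [
        "darker", "lighter", "darker", "lighter",
    ]


# ---------------------------------------------------------------------------
# Learning model


def test_degenerate_variance_limit_matches_plain_logistic():
    """With no between-bee heterogeneity the fit collapses to ordinary
    logistic regression (independent IRLS oracle)."""
    table = ss.simulate_choices(
        beta0=0.5, beta1=2.0, sigma_b=0.0, sigma_s=0.0, n_bees=40, seed=1
    )
    fit = bh.fit_learning_model(table, "experience")
    x = (table["trial"] - 1) / (table["trial"].max() - 1)
    X = np.column_stack([np.ones(len(table)), x])
    glm = sm.GLM(table["correct"], X, family=sm.families.Binomial()).fit()
    assert fit.fixed_effects["intercept"] == pytest.approx(glm.params.iloc[0], abs=0.05)
    assert fit.fixed_effects["experience"] == pytest.approx(glm.params.iloc[1], abs=0.05)
    # truth recovery within 3 SE
    for name, truth, se in (
        ("intercept", 0.5, glm.bse.iloc[0]),
        ("experience", 2.0, glm.bse.iloc[1]),
    ):
        assert abs(fit.fixed_effects[name] - truth) < 3 * se


def test_balanced_fifty_percent_gives_zero_intercept():
    rows = []
    for bee, pattern in (("a", [1, 0]), ("b", [0, 1]), ("c", [1, 0]), ("d", [0, 1])):
        correct = np.tile(pattern, 25)
        rows.append(pd.DataFrame({
            "bee_id": bee, "trial": np.arange(1, 51), "condition": "pol", "correct": correct,
        }))
    table = pd.concat(rows, ignore_index=True)
    fit = bh.fit_learning_model(table, "null")
    assert fit.fixed_effects["intercept"] == pytest.approx(0.0, abs=0.05)


def test_fit_validates_inputs():
    table = ss.simulate_choices(n_bees=1, n_trials=10, seed=0)
    with pytest.raises(ValueError, match="2 bees"):
        bh.fit_learning_model(table)
    table2 = ss.simulate_choices(n_bees=3, n_trials=10, seed=0)
    with pytest.raises(ValueError, match="spec"):
        bh.fit_learning_model(table2, "quadratic")


def test_aic_identity_and_determinism():
    table = ss.simulate_choices(n_bees=6, seed=8)
    a = bh.fit_learning_model(table, "experience")
    b = bh.fit_learning_model(table, "experience")
    assert a.deviance == b.deviance  # deterministic given data
    assert a.aic == pytest.approx(a.deviance + 2 * a.n_params)


def test_parameter_recovery_at_experimental_scale():
    """Across 200 simulated sessions (9 bees x 100 trials) the median slope
    estimate lands within 15% of the generating value."""
    truth = np.log(3.0)
    estimates = []
    for rep in range(200):
        table = ss.simulate_choices(n_bees=9, seed=60000 + rep)
        fit = bh.fit_learning_model(table, "experience")
        estimates.append(fit.fixed_effects["experience"])
    assert np.median(estimates) == pytest.approx(truth, rel=0.15)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_laplace_fit_matches_lme4(tmp_path):
    """Independent cross-check: lme4's Laplace GLMM fit on the same data.

    Both routes maximize the Laplace-approximate marginal likelihood of the
    random-intercept + uncorrelated-random-slope logistic model, so the
    deviances and fixed effects should agree to optimizer tolerance.
    """
    table = ss.simulate_choices(
        beta0=-0.2, beta1=1.2, sigma_b=0.8, sigma_s=0.8, n_bees=12, seed=42
    )
    fit = bh.fit_learning_model(table, "experience")
    csv = tmp_path / "choices.csv"
    table.assign(x=(table["trial"] - 1) / 99).to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(correct ~ x + (1 | bee_id) + (0 + x | bee_id),
                   family = binomial, data = d)
        cat(sprintf('{{"deviance": %.6f, "beta0": %.6f, "beta1": %.6f}}',
            -2 * as.numeric(logLik(m)), fixef(m)[1], fixef(m)[2]))
        """
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
    )
    ref = json.loads(out.stdout.strip().splitlines()[-1])
    assert fit.deviance == pytest.approx(ref["deviance"], abs=0.1)
    assert fit.fixed_effects["intercept"] == pytest.approx(ref["beta0"], abs=0.05)
    assert fit.fixed_effects["experience"] == pytest.approx(ref["beta1"], abs=0.05)


# ---------------------------------------------------------------------------
# Nested comparison


def _fit_shell(deviance, n_params, names, spec="experience", slope=True):
    return bh.LearningFit(
        spec=spec, fixed_effects={n: 0.0 for n in names}, sigma_b=0.1,
        sigma_s=0.1 if slope else None, deviance=deviance,
        aic=deviance + 2 * n_params, n_params=n_params, converged=True,
        n_bees=9, n_obs=900, random_slope=slope,
    )


def test_compare_nested_identities():
    full = _fit_shell(900.0, 4, ("intercept", "experience"))
    null = _fit_shell(910.0, 3, ("intercept",), spec="null")
    out = bh.compare_nested(full, null)
    assert out["delta_deviance"] == pytest.approx(10.0)
    assert out["delta_df"] == 1
    assert out["delta_aic"] == pytest.approx(out["delta_deviance"] - 2 * out["delta_df"])
    assert out["p_value"] == pytest.approx(stats.chi2.sf(10.0, 1))

    equal = bh.compare_nested(
        _fit_shell(900.0, 4, ("intercept", "experience")),
        _fit_shell(900.0, 3, ("intercept",), spec="null"),
    )
    assert equal["delta_deviance"] == 0.0 and equal["p_value"] == 1.0


def test_compare_nested_rejects_non_nested():
    full = _fit_shell(900.0, 4, ("intercept", "experience"))
    other = _fit_shell(905.0, 3, ("intercept", "condition[x]"), spec="null")
    with pytest.raises(ValueError, match="not nested"):
        bh.compare_nested(full, other)
    worse = _fit_shell(890.0, 3, ("intercept",), spec="null")
    with pytest.raises(ValueError, match="below full"):
        bh.compare_nested(full, worse)
    slope_mismatch = _fit_shell(910.0, 2, ("intercept",), spec="null", slope=False)
    with pytest.raises(ValueError, match="random-effect"):
        bh.compare_nested(full, slope_mismatch)


def test_p_value_monotone_in_delta_deviance():
    deltas = np.linspace(0.0, 30.0, 40)
    ps = [bh.likelihood_ratio_test(d, 1) for d in deltas]
    assert np.all(np.diff(ps) < 0)
    with pytest.raises(ValueError, match="delta_df"):
        bh.likelihood_ratio_test(1.0, 0)


def test_fit_report_shape():
    table = ss.simulate_choices(n_bees=6, seed=17)
    report = bh.fit_report(table, treatment="DF-like")
    assert set(report) == {
        "treatment", "deviance_null", "deviance_full", "delta_deviance",
        "df", "p", "aic_null", "aic_full",
    }
    assert report["aic_null"] - report["aic_full"] == pytest.approx(
        report["delta_deviance"] - 2 * report["df"]
    )


# ---------------------------------------------------------------------------
# Interaction test


def test_interaction_test_needs_two_levels():
    table = ss.simulate_choices(n_bees=3, n_trials=10, seed=0)  # constant condition
    with pytest.raises(ValueError, match="levels"):
        bh.interaction_test(table)


def test_interaction_pvalues_uniform_under_permuted_labels():
    """With condition labels randomly permuted (and thus uninformative), the
    interaction p-value is Uniform(0,1): rejection at 0.05 stays within 2 SE
    of nominal and the KS test finds no deviation across 500 sessions."""
    pvals = []
    for rep in range(500):
        table = ss.simulate_choices(n_bees=9, seed=40000 + rep, dfic=True)
        rng = np.random.default_rng(50000 + rep)
        table = table.assign(condition=rng.permutation(table["condition"].to_numpy()))
        pvals.append(bh.interaction_test(table)["p_value"])
    pvals = np.asarray(pvals)
    rate = np.mean(pvals < 0.05)
    se = np.sqrt(0.05 * 0.95 / 500)
    assert abs(rate - 0.05) < 2 * se
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Learning curves


def test_learning_curve_trivial_bins():
    table = pd.DataFrame({
        "bee_id": "a", "trial": np.arange(1, 21), "condition": "pol",
        "correct": [1] * 10 + [1] * 5 + [0] * 5,
    })
    table = pd.concat([table, table.assign(bee_id="b")], ignore_index=True)
    curve = bh.learning_curve(table, bin_size=10)
    assert len(curve) == 2
    assert curve.loc[0, "proportion"] == 1.0
    assert curve.loc[0, "ci_high"] == pytest.approx(1.0)
    assert curve.loc[1, "proportion"] == 0.5
    assert curve.loc[1, "ci_low"] < 0.5 < curve.loc[1, "ci_high"]


def test_learning_curve_wilson_vs_clopper_pearson():
    """Wilson endpoints stay within the documented divergence (<0.03 at
    n=100) of the exact Clopper-Pearson interval."""
    table = ss.simulate_choices(n_bees=1, n_trials=100, seed=9).assign(bee_id="solo")
    curve = bh.learning_curve(table, bin_size=100)
    lo, hi = proportion_confint(
        int(curve.loc[0, "successes"]), int(curve.loc[0, "n"]), method="beta"
    )
    assert curve.loc[0, "ci_low"] == pytest.approx(lo, abs=0.03)
    assert curve.loc[0, "ci_high"] == pytest.approx(hi, abs=0.03)


def test_learning_curve_rejects_empty():
    with pytest.raises(ValueError, match="empty"):
        bh.learning_curve(pd.DataFrame(columns=["bee_id", "trial", "condition", "correct"]))
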