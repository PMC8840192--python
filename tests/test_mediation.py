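"""Natural effect estimation: algebraic oracles, decomposition, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from clrmediate.factors import DietFactorSpec
from clrmediate.mediation import (
    bonferroni_threshold,
    bootstrap_mediation,
    estimate_natural_effects,
    expand_counterfactuals,
    fit_imputation_model,
    fit_natural_effect_model,
    percent_mediated,
    transform_mediator,
)
from clrmediate.synthetic import generate_sem_cohort

from conftest import make_config, planted_truth


def _random_cohort(rng, n=60, n_groups=3, n_conf=2, gamma=0.7, beta=1.0):
    groups = [chr(ord("a") + i) for i in range(n_groups)]
    g = rng.choice(groups, n)
    C = rng.normal(size=(n, n_conf))
    M = rng.normal(size=n) + 0.5 * (g == groups[1]) + C @ rng.normal(size=n_conf) * 0.2
    Y = (rng.normal(size=n) + gamma * M + beta * (g == groups[-1])
         + C @ rng.normal(size=n_conf) * 0.3)
    return Y, g, M, C


def _product_of_coefficients(Y, g, M, C, reference):
    """Independent closed-form oracle for the linear no-interaction case."""
    levels = [reference] + sorted(set(g) - {reference})
    D = np.column_stack([(g == lev).astype(float) for lev in levels[1:]])
    n = len(Y)
    X_out = np.column_stack([np.ones(n), D, M, C])
    b = np.linalg.solve(X_out.T @ X_out, X_out.T @ Y)
    X_med = np.column_stack([np.ones(n), D, C])
    a = np.linalg.solve(X_med.T @ X_med, X_med.T @ M)
    L = len(levels)
    nde = b[1:L]
    nie = b[L] * a[1:L]
    return levels[1:], nde, nie


class TestImputationModel:
    def test_zero_outcome_gives_zero_coefficients(self, rng):
        _, g, M, C = _random_cohort(rng)
        fit = fit_imputation_model(np.zeros(60), g, M, C, reference="a")
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.exposure_coefs, 0.0, atol=1e-10)
        assert fit.mediator_coef == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_solve(self, rng):
        Y, g, M, C = _random_cohort(rng)
        fit = fit_imputation_model(Y, g, M, C, reference="a")
        levels = ["a", "b", "c"]
        D = np.column_stack([(g == lev).astype(float) for lev in levels[1:]])
        X = np.column_stack([np.ones(60), D, M, C])
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-8)
        assert np.allclose(fit.exposure_coefs[1:], beta[1:3], rtol=1e-8)
        assert fit.mediator_coef == pytest.approx(beta[3], rel=1e-8)

    def test_recovers_mediator_slope_on_synthetic_cohort(self):
        cfg = make_config(n_per_group=2000, n_groups=3, noise_sd=0.05, seed=2)
        truth = planted_truth(cfg, alpha=1.0, gamma=0.5, beta=0.3)
        cohort, Y, _ = generate_sem_cohort(cfg, truth)
        fit = fit_imputation_model(
            Y.iloc[:, 0], cohort["group"], np.log(cohort["diet0"]),
            cohort[["age", "sex", "energy", "bmi", "antibiotics"]],
            reference="g0")
        # residual sd 0.05 over n=6000: the slope's MC error is ~1e-3
        assert fit.mediator_coef == pytest.approx(0.5, abs=0.01)

    def test_constant_mediator_rejected(self, rng):
        Y, g, _, C = _random_cohort(rng)
        with pytest.raises(ValueError, match="constant"):
            fit_imputation_model(Y, g, np.ones(60), C, reference="a")

    def test_collinear_confounders_named(self, rng):
        Y, g, M, _ = _random_cohort(rng)
        C = np.column_stack([M, M])
        with pytest.raises(ValueError, match="collinear"):
            fit_imputation_model(Y, g, M, C, reference="a")


class TestExpansion:
    def test_row_count_is_n_times_levels(self, rng):
        Y, g, M, C = _random_cohort(rng)
        fit = fit_imputation_model(Y, g, M, C, reference="a")
        # expanding two subjects over the 3 observed levels gives 6 rows
        exp = expand_counterfactuals(g[:2], M[:2], fit, C[:2])
        assert len(exp.yhat) == 2 * 3
        # x1 constant within subject, equal to the observed exposure
        lookup = np.array(fit.levels)
        assert list(lookup[exp.x1[exp.subject == 0]]) == [g[0]] * 3
        assert list(lookup[exp.x1[exp.subject == 1]]) == [g[1]] * 3

    def test_factual_rows_equal_fitted_values(self, rng):
        Y, g, M, C = _random_cohort(rng)
        fit = fit_imputation_model(Y, g, M, C, reference="a")
        exp = expand_counterfactuals(g, M, fit, C)
        factual = exp.yhat[exp.x0 == exp.x1]
        codes = np.array([fit.levels.index(v) for v in g])
        fitted = fit.predict(codes, M, C)
        assert np.allclose(np.sort(factual), np.sort(fitted), atol=1e-10)

    def test_within_subject_contrasts_identical_across_subjects(self, rng):
        Y, g, M, C = _random_cohort(rng)
        fit = fit_imputation_model(Y, g, M, C, reference="a")
        exp = expand_counterfactuals(g, M, fit, C)
        L = len(fit.levels)
        per_subject = exp.yhat.reshape(-1, L)
        contrasts = per_subject - per_subject[:, [0]]
        assert np.allclose(contrasts, contrasts[0], atol=1e-10)
        assert np.allclose(contrasts[0], fit.exposure_coefs, atol=1e-10)

    def test_unseen_level_rejected(self, rng):
        Y, g, M, C = _random_cohort(rng)
        fit = fit_imputation_model(Y, g, M, C, reference="a")
        g_bad = g.copy()
        g_bad[0] = "zz"
        with pytest.raises(ValueError, match="unseen"):
            expand_counterfactuals(g_bad, M, fit, C)


class TestNaturalEffectModel:
    @pytest.mark.parametrize("trial", range(10))
    def test_equals_product_of_coefficients_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        Y, g, M, C = _random_cohort(rng)
        ne = estimate_natural_effects(Y, g, M, C, reference="a")
        groups, nde, nie = _product_of_coefficients(Y, g, M, C, "a")
        assert list(ne.nde.index) == groups
        np.testing.assert_allclose(ne.nde.to_numpy(), nde, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(ne.nie.to_numpy(), nie, rtol=1e-8, atol=1e-10)

    def test_decomposition_identity(self, rng):
        Y, g, M, C = _random_cohort(rng)
        ne = estimate_natural_effects(Y, g, M, C, reference="b")
        np.testing.assert_allclose(
            ne.te.to_numpy(), (ne.nde + ne.nie).to_numpy(), atol=1e-10)

    def test_total_effect_matches_unmediated_regression(self, rng):
        # the OLS omitted-variable identity: coefficients of Y ~ X + C equal
        # nde + nie from the mediated decomposition, exactly
        Y, g, M, C = _random_cohort(rng)
        ne = estimate_natural_effects(Y, g, M, C, reference="a")
        n = len(Y)
        D = np.column_stack([(g == lev).astype(float) for lev in ("b", "c")])
        X = np.column_stack([np.ones(n), D, C])
        b = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(ne.te.to_numpy(), b[1:3], rtol=1e-8)

    def test_zero_mediator_pathway_gives_zero_nie(self, rng):
        Y, g, M, C = _random_cohort(rng)
        fit = fit_imputation_model(Y, g, M, C, reference="a")
        fit.mediator_coef = 0.0
        ne = fit_natural_effect_model(expand_counterfactuals(g, M, fit, C))
        assert np.allclose(ne.nie.to_numpy(), 0.0, atol=1e-12)

    def test_group_relabelling_permutes_effects(self, rng):
        Y, g, M, C = _random_cohort(rng)
        ne = estimate_natural_effects(Y, g, M, C, reference="a")
        swap = {"a": "a", "b": "q", "c": "b"}
        g2 = np.array([swap[v] for v in g])
        ne2 = estimate_natural_effects(Y, g2, M, C, reference="a")
        assert ne2.nde["q"] == pytest.approx(ne.nde["b"], rel=1e-10)
        assert ne2.nie["b"] == pytest.approx(ne.nie["c"], rel=1e-10)

    def test_recovers_planted_effects_on_synthetic_cohort(self):
        cfg = make_config(n_per_group=1000, n_groups=5, noise_sd=0.2, seed=4)
        truth = planted_truth(cfg, alpha=1.0, gamma=0.5, beta=0.3, group="g1")
        cohort, Y, _ = generate_sem_cohort(cfg, truth)
        ne = estimate_natural_effects(
            Y.iloc[:, 0], cohort["group"], np.log(cohort["diet0"]),
            cohort[["age", "sex", "energy", "bmi", "antibiotics"]],
            reference="g0")
        # 3-sigma Monte-Carlo bands at this n and noise level
        assert ne.nie["g1"] == pytest.approx(0.5, abs=0.05)
        assert ne.nde["g1"] == pytest.approx(0.3, abs=0.05)
        assert ne.te["g1"] == pytest.approx(0.8, abs=0.07)


class TestBootstrap:
    def test_identical_seed_identical_ses(self, rng):
        Y, g, M, C = _random_cohort(rng, n=90)
        kw = dict(reference="a", n_boot=50, seed=77)
        e1 = bootstrap_mediation(Y, g, M, C, **kw)
        e2 = bootstrap_mediation(Y, g, M, C, **kw)
        pd.testing.assert_frame_equal(e1.effects, e2.effects)

    def test_noisy_outcome_gives_positive_ses(self, rng):
        Y, g, M, C = _random_cohort(rng, n=90)
        est = bootstrap_mediation(Y, g, M, C, reference="a", n_boot=50, seed=1)
        assert (est.effects[["se_te", "se_nde", "se_nie"]] > 0).all().all()

    def test_stratified_resampling_keeps_all_levels(self, rng):
        # tiny minority group: unstratified resampling would often drop it
        g = np.array(["a"] * 50 + ["b"] * 50 + ["c"] * 3)
        M = rng.normal(size=103)
        Y = rng.normal(size=103) + 0.5 * M
        est = bootstrap_mediation(Y, g, M, None, reference="a",
                                  n_boot=50, seed=5)
        assert est.effects.loc["c", "se_nie"] > 0

    def test_effects_table_schema(self, rng):
        Y, g, M, C = _random_cohort(rng, n=90)
        est = bootstrap_mediation(Y, g, M, C, reference="a", n_boot=25, seed=9)
        assert list(est.effects.index) == ["b", "c"]
        for col in ("te", "nde", "nie", "se_te", "se_nde", "se_nie",
                    "p_te", "p_nde", "p_nie", "percent_mediated"):
            assert col in est.effects.columns
        assert est.effects[["p_te", "p_nde", "p_nie"]].le(1).all().all()


class TestScalars:
    @pytest.mark.parametrize("nie,te,expected", [
        (0.0, 2.0, 0.0),
        (1.0, 2.0, 50.0),
        (-0.5, 1.25, -40.0),
    ])
    def test_percent_mediated(self, nie, te, expected):
        assert percent_mediated(nie, te) == pytest.approx(expected)

    def test_percent_mediated_degenerate_total_is_na(self):
        assert np.isnan(percent_mediated(0.5, 0.0))

    @pytest.mark.parametrize("args,expected", [
        ((0.05, 1, 1, 1), 0.05),
        ((0.01, 10, 2, 3), 0.01 / 60),
    ])
    def test_bonferroni_threshold(self, args, expected):
        assert bonferroni_threshold(*args) == pytest.approx(expected)

    def test_bonferroni_study_grid_value(self):
        # 63 genera x 15 factors x 4 comparisons -> 1.32e-5 (rounds to 1.3e-5)
        t = bonferroni_threshold(0.05, 63, 15, 4)
        assert float(f"{t:.3g}") == pytest.approx(1.32e-5)
        assert float(f"{t:.2g}") == pytest.approx(1.3e-5)

    def test_bonferroni_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="n_factors"):
            bonferroni_threshold(0.05, 3, 0, 2)


class TestMediatorTransform:
    def test_log_scale_with_zero_offset(self):
        spec = DietFactorSpec("intake", "moderation", log_transform=True)
        v = np.array([0.0, 1.0, 4.0])
        out = transform_mediator(v, spec)
        # zeros offset by half the smallest positive value (0.5)
        assert np.allclose(out, np.log(v + 0.5))

    def test_index_factor_untransformed(self):
        spec = DietFactorSpec("hei", "index", log_transform=False)
        v = np.array([60.0, 75.0])
        assert np.allclose(transform_mediator(v, spec), v)

    def test_negative_intake_rejected(self):
        spec = DietFactorSpec("intake", "adequacy")
        with pytest.raises(ValueError, match="negative"):
            transform_mediator(np.array([-1.0, 2.0]), spec)
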