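"""Penalized-likelihood fitting, the multinomial merge, standardization, CIs."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
from scipy.special import expit

from bst.errors import AliasingError
from bst.firth import (
    breed_probability_table,
    fit_category_models,
    fit_firth_logistic,
    merge_binomials,
    population_age_distribution,
    simulate_confidence_intervals,
    standardized_breed_probabilities,
    EhrDesign,
    FirthFit,
)


def _penalized_loglik_oracle(X, y, beta):
    """Independent straight-from-the-definition penalized log-likelihood."""
    eta = X @ beta
    pi = expit(eta)
    ll = np.sum(y * np.log(pi) + (1 - y) * np.log1p(-pi))
    w = pi * (1 - pi)
    info = X.T @ (X * w[:, None])
    return ll + 0.5 * np.linalg.slogdet(info)[1]


class TestFirthFit:
    def test_intercept_only_balanced_is_zero(self):
        X = np.ones((10, 1))
        y = np.array([1] * 5 + [0] * 5, dtype=float)
        fit = fit_firth_logistic(X, y)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("n, k", [(10, 10), (10, 7), (25, 0), (8, 3)])
    def test_intercept_only_closed_form(self, n, k):
        """Penalized mode is p = (k + 1/2) / (n + 1), even at k = n or 0."""
        X = np.ones((n, 1))
        y = np.array([1] * k + [0] * (n - k), dtype=float)
        fit = fit_firth_logistic(X, y)
        p_hat = (k + 0.5) / (n + 1)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(p_hat / (1 - p_hat)),
                                                    abs=1e-6)

    def test_intercept_only_matches_grid_search(self):
        """1-D grid search over the penalized likelihood finds the same mode."""
        n, k = 10, 10
        X = np.ones((n, 1))
        y = np.array([1.0] * k)
        grid = np.linspace(-2, 8, 20001)
        values = [_penalized_loglik_oracle(X, y, np.array([b])) for b in grid]
        fit = fit_firth_logistic(X, y)
        assert fit.coefficients[0] == pytest.approx(grid[np.argmax(values)],
                                                    abs=1e-3)
        assert fit.coefficients[0] == pytest.approx(np.log(10.5 / 0.5), abs=1e-6)

    def test_complete_separation_matches_independent_maximizer(self):
        """x perfectly predicts y: ML diverges, the penalized mode is finite
        and must match an independent 2-D maximization to 1e-4."""
        X = np.column_stack([np.ones(10), np.repeat([0.0, 1.0], 5)])
        y = np.repeat([0.0, 1.0], 5)
        fit = fit_firth_logistic(X, y)
        assert fit.converged
        assert np.all(np.isfinite(fit.coefficients))

        res = scipy.optimize.minimize(
            lambda b: -_penalized_loglik_oracle(X, y, b),
            x0=np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10000})
        assert np.allclose(fit.coefficients, res.x, atol=1e-4)
        # symmetry of the 2x2 layout: intercept = -slope/2
        assert fit.coefficients[0] == pytest.approx(-fit.coefficients[1] / 2,
                                                    abs=1e-6)

    def test_penalized_loglik_nondecreasing(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
        y = (rng.random(200) < expit(X @ np.array([0.3, 1.0, -0.5]))).astype(float)
        fit = fit_firth_logistic(X, y)
        trace = np.array(fit.pll_trace)
        assert (np.diff(trace) >= -1e-9).all()

    def test_rank_deficiency_names_aliased_column(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        y = (np.arange(20) % 2).astype(float)
        with pytest.raises(AliasingError) as err:
            fit_firth_logistic(X, y, term_names=["int", "a", "b"])
        assert "b" in err.value.aliased_columns or "a" in err.value.aliased_columns

    def test_covariance_is_symmetric_psd(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(300), rng.standard_normal((300, 3))])
        y = (rng.random(300) < 0.4).astype(float)
        fit = fit_firth_logistic(X, y)
        assert np.allclose(fit.covariance, fit.covariance.T)
        assert np.linalg.eigvalsh(fit.covariance).min() > 0

    def test_nonconvergence_is_flagged_not_silent(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(500), rng.standard_normal((500, 2))])
        y = (rng.random(500) < expit(X @ np.array([0.0, 2.0, -1.0]))).astype(float)
        fit = fit_firth_logistic(X, y, max_iter=1)
        assert not fit.converged
        assert np.isfinite(fit.max_modified_score)


class TestMerge:
    def test_symmetric_case(self):
        assert np.allclose(merge_binomials(0.0, 0.0), [1 / 3] * 3)

    def test_softmax_arithmetic(self):
        p = merge_binomials(-20.0, 0.0)
        assert p[0] == pytest.approx(0.0, abs=1e-8)
        assert p[1] == pytest.approx(0.5, abs=1e-8)
        assert p[2] == pytest.approx(0.5, abs=1e-8)

    def test_triples_sum_to_one(self):
        rng = np.random.default_rng(3)
        eta_u = rng.uniform(-30, 30, size=500)
        eta_o = rng.uniform(-30, 30, size=500)
        p = merge_binomials(eta_u, eta_o)
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-12)
        assert (p >= 0).all() and (p <= 1).all()

    def test_reproduces_each_binomial_conditionally(self):
        """Conditioned on not-the-other-category, the merge gives back the
        binomial probability expit(eta)."""
        eta_u, eta_o = 0.7, -1.2
        p = merge_binomials(eta_u, eta_o)
        assert p[0] / (p[0] + p[1]) == pytest.approx(expit(eta_u))
        assert p[2] / (p[2] + p[1]) == pytest.approx(expit(eta_o))


def _toy_design(n_breeds=3, ages=(2, 5), include_interactions=False):
    frame = pd.DataFrame(
        [(f"breed_{i}", a, s)
         for i in range(1, n_breeds + 1) for a in ages
         for s in ("female", "male")],
        columns=["breed", "age_years", "sex"])
    design = EhrDesign(breed_levels=sorted(frame["breed"].unique()),
                       sex_levels=["female", "male"],
                       age_levels=sorted(set(ages)),
                       include_interactions=include_interactions)
    return frame, design


def _fit_with(design, coef):
    p = len(design.term_names)
    beta = np.zeros(p)
    for name, value in coef.items():
        beta[design.term_names.index(name)] = value
    return FirthFit(coefficients=beta, covariance=np.zeros((p, p)),
                    penalized_loglik=0.0, n_iterations=0, converged=True,
                    term_names=list(design.term_names))


class TestStandardization:
    def test_null_model_gives_equal_thirds(self):
        _, design = _toy_design()
        fit = _fit_with(design, {})
        out = standardized_breed_probabilities(
            fit, fit, design, {2: 0.3, 5: 0.7})
        for col in ("p_underweight", "p_ideal", "p_overweight_obese"):
            assert np.allclose(out[col], 1 / 3, atol=1e-12)

    def test_matches_enumeration_oracle(self):
        """2 ages x 2 sexes with hand-set coefficients equals the hand-
        weighted average of the merged probabilities."""
        _, design = _toy_design()
        fit_u = _fit_with(design, {"(Intercept)": -1.0, "age": 0.1,
                                   "sex[male]": -0.2, "breed[breed_2]": 0.5})
        fit_o = _fit_with(design, {"(Intercept)": 0.3, "age": -0.05,
                                   "breed[breed_3]": 0.8})
        ages = {2: 0.4, 5: 0.6}
        out = standardized_breed_probabilities(fit_u, fit_o, design, ages)
        out = out.set_index("breed")

        def eta(fit, breed, age, male):
            c = dict(zip(fit.term_names, fit.coefficients))
            return (c["(Intercept)"] + c.get(f"breed[{breed}]", 0.0)
                    + c["age"] * age + c["sex[male]"] * male)

        for breed in design.breed_levels:
            expected = np.zeros(3)
            for age, w in ages.items():
                for male in (0.0, 1.0):
                    expected += w * 0.5 * merge_binomials(
                        eta(fit_u, breed, age, male), eta(fit_o, breed, age, male))
            got = out.loc[breed, ["p_underweight", "p_ideal",
                                  "p_overweight_obese"]].to_numpy(dtype=float)
            assert np.allclose(got, expected, atol=1e-12)

    def test_point_mass_age_reduces_to_sex_average(self):
        _, design = _toy_design(ages=(5,))
        fit_u = _fit_with(design, {"(Intercept)": -0.5, "age": 0.08,
                                   "sex[male]": 0.3})
        fit_o = _fit_with(design, {"(Intercept)": 0.1, "sex[male]": -0.4})
        out = standardized_breed_probabilities(fit_u, fit_o, design, {5: 1.0})
        c_u = dict(zip(fit_u.term_names, fit_u.coefficients))
        expected = 0.5 * (
            merge_binomials(-0.5 + 0.4, 0.1)
            + merge_binomials(-0.5 + 0.4 + 0.3, 0.1 - 0.4))
        got = out.set_index("breed").loc[
            "breed_1", ["p_underweight", "p_ideal", "p_overweight_obese"]]
        assert np.allclose(got.to_numpy(dtype=float), expected, atol=1e-12)

    def test_weights_must_sum_to_one(self):
        _, design = _toy_design()
        fit = _fit_with(design, {})
        with pytest.raises(ValueError):
            standardized_breed_probabilities(fit, fit, design, {2: 0.3, 5: 0.3})

    def test_probability_triples_sum_to_one_on_real_fit(self, small_sim_config):
        from bst.cohort import recode_bcs_column, select_random_visit
        from bst.synthetic import generate_ehr_cohort

        import warnings

        e, _ = generate_ehr_cohort(small_sim_config)
        records = recode_bcs_column(select_random_visit(e, 7))
        with warnings.catch_warnings():
            # tiny cohort: empty breed interaction cells may be dropped
            warnings.simplefilter("ignore", UserWarning)
            fit_u, fit_o, design = fit_category_models(records)
        ages = population_age_distribution(records)
        out = standardized_breed_probabilities(fit_u, fit_o, design, ages)
        totals = out[["p_underweight", "p_ideal", "p_overweight_obese"]].sum(axis=1)
        assert np.allclose(totals, 1.0, atol=1e-10)

    def test_sex_reference_recode_leaves_probabilities_unchanged(self):
        """Treatment recoding is a reparameterization: standardized
        probabilities are invariant to which sex is the reference."""
        rng = np.random.default_rng(8)
        n = 2000
        frame = pd.DataFrame({
            "breed": rng.choice(["a", "b", "c"], size=n),
            "sex": rng.choice(["female", "male"], size=n),
            "age_years": rng.integers(1, 10, size=n),
        })
        eta = (-0.5 + 0.4 * (frame["breed"] == "b") + 0.1 * frame["age_years"]
               + 0.3 * (frame["sex"] == "male"))
        frame["bcs_category"] = np.where(
            rng.random(n) < expit(eta), "overweight_obese",
            np.where(rng.random(n) < 0.15, "underweight", "ideal"))
        recoded = frame.assign(sex=frame["sex"].map(
            {"female": "z_female", "male": "male"}))

        ages = {a: 1 / 9 for a in range(1, 10)}
        tables = []
        for data in (frame, recoded):
            design = EhrDesign.from_records(data, include_interactions=True)
            fit_u, fit_o, design = fit_category_models(data, design,
                                                       tol=1e-10)
            tables.append(standardized_breed_probabilities(
                fit_u, fit_o, design, ages))
        a, b = tables
        assert np.allclose(
            a[["p_underweight", "p_ideal", "p_overweight_obese"]],
            b[["p_underweight", "p_ideal", "p_overweight_obese"]], atol=1e-10)


class TestSimulationCIs:
    def test_zero_covariance_gives_zero_width(self):
        _, design = _toy_design()
        fit = _fit_with(design, {"(Intercept)": -0.3, "age": 0.05})
        points = standardized_breed_probabilities(fit, fit, design, {2: 1.0})
        cis = simulate_confidence_intervals(fit, fit, design, {2: 1.0},
                                            n_draws=200, seed=1)
        merged = points.merge(cis, on="breed")
        for cat in ("underweight", "ideal", "overweight_obese"):
            assert np.allclose(merged[f"ci_low_{cat}"], merged[f"p_{cat}"])
            assert np.allclose(merged[f"ci_high_{cat}"], merged[f"p_{cat}"])

    def test_same_seed_reproducible(self):
        _, design = _toy_design()
        fit = _fit_with(design, {"(Intercept)": -0.3})
        fit.covariance = 0.05 * np.eye(len(design.term_names))
        a = simulate_confidence_intervals(fit, fit, design, {2: 0.5, 5: 0.5},
                                          n_draws=300, seed=9)
        b = simulate_confidence_intervals(fit, fit, design, {2: 0.5, 5: 0.5},
                                          n_draws=300, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_ci_brackets_point_estimate(self):
        _, design = _toy_design()
        fit = _fit_with(design, {"(Intercept)": -0.4, "age": 0.02})
        fit.covariance = 0.02 * np.eye(len(design.term_names))
        table = breed_probability_table(fit, fit, design, {2: 0.5, 5: 0.5},
                                        n_draws=400, seed=2)
        for cat in ("underweight", "ideal", "overweight_obese"):
            assert (table[f"ci_low_{cat}"] <= table[f"p_{cat}"] + 1e-9).all()
            assert (table[f"ci_high_{cat}"] >= table[f"p_{cat}"] - 1e-9).all()

    def test_small_draw_count_warns(self):
        _, design = _toy_design()
        fit = _fit_with(design, {})
        with pytest.warns(UserWarning):
            simulate_confidence_intervals(fit, fit, design, {2: 1.0},
                                          n_draws=50, seed=0)

    def test_non_psd_covariance_rejected(self):
        _, design = _toy_design()
        fit = _fit_with(design, {})
        bad = -np.eye(len(design.term_names))
        fit.covariance = bad
        with pytest.raises(ValueError):
            simulate_confidence_intervals(fit, fit, design, {2: 1.0},
                                          n_draws=200, seed=0)


def test_firth_approaches_ml_without_separation():
    """On well-behaved data the penalty vanishes as n grows: at n = 50,000
    with 3 covariates the Firth and ML estimates agree to 0.02."""
    import statsmodels.api as sm

    rng = np.random.default_rng(12)
    n = 50_000
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
    beta = np.array([0.2, 0.8, -0.5, 0.3])
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    firth = fit_firth_logistic(X, y)
    ml = sm.Logit(y, X).fit(disp=0)
    assert np.abs(firth.coefficients - ml.params).max() < 0.02
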