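import numpy as np
import pandas as pd
import pytest

from droughtgam import (
    build_design,
    fit_penalized_logistic,
    make_knots,
    model_residuals,
    spline_basis,
)
from droughtgam.gam import (
    DEFAULT_COVARIATES,
    DesignMatrix,
    SeparationError,
    _eta,
    _psd_clip,
)
from droughtgam.geo import unit_vectors
from .oracles import logistic_deviance, newton_logistic


def _design_from_arrays(X, y, coords, drought_columns=()):
    return DesignMatrix(X=X, y=y, column_names=[f"c{j}" for j in range(X.shape[1])],
                        coords=coords, outcome="physical",
                        drought_columns=list(drought_columns))


class TestBuildDesign:
    def test_column_count(self, population):
        design = build_design(population, "physical")
        n_surveys = population["survey_id"].nunique()
        expected = 1  # intercept
        for name, levels in DEFAULT_COVARIATES.items():
            expected += 1 if levels is None else len(levels) - 1
        expected += 3 + (n_surveys - 1)  # drought dummies + survey dummies
        present = set(population["drought_category"])
        expected -= len({"moderate", "severe", "extreme"} - present)
        assert design.n_columns == expected
        assert design.n_obs == len(population)
        assert design.coords.shape == (len(population), 2)

    def test_two_surveys_one_dummy(self, population):
        two = population[population["survey_id"].isin(["s000", "s001"])]
        design = build_design(two, "sexual")
        assert sum(c.startswith("survey[") for c in design.column_names) == 1

    def test_unknown_outcome_rejected(self, population):
        with pytest.raises(ValueError):
            build_design(population, "height")

    def test_all_nondrought_drops_dummies(self, population, caplog):
        records = population.copy()
        records["drought_category"] = "none"
        records["drought_binary"] = "normal"
        with caplog.at_level("WARNING"):
            design = build_design(records, "physical")
        assert design.drought_columns == []
        assert "unidentifiable" in caplog.text

    def test_binary_drought_single_column(self, population):
        design = build_design(population, "physical", drought="binary")
        assert design.drought_columns == ["drought[drought]"]

    def test_references_recorded(self, population):
        design = build_design(population, "physical")
        assert design.references["drought"] == "none"
        assert design.references["survey"] == "s000"
        assert design.references["age_band"] == "<20"


class TestMakeKnots:
    def test_zero_knots(self, rng):
        assert make_knots(rng.uniform(0, 5, (30, 2)), 0).shape == (0, 2)

    def test_all_points(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.5], [0.0, 0.0]])
        knots = make_knots(coords, 3)
        assert sorted(map(tuple, knots)) == sorted(map(tuple, np.unique(coords, axis=0)))

    def test_too_many_rejected(self):
        with pytest.raises(ValueError, match="smaller K"):
            make_knots(np.array([[0.0, 0.0], [1.0, 1.0]]), 3)

    def test_deterministic(self, rng):
        coords = rng.uniform(0, 5, (100, 2))
        np.testing.assert_array_equal(make_knots(coords, 10, seed=3),
                                      make_knots(coords, 10, seed=3))

    def test_knots_inside_bounding_cap(self, rng):
        coords = rng.uniform(0, 5, (200, 2))
        knots = make_knots(coords, 20, seed=0)
        u = unit_vectors(coords[:, 0], coords[:, 1])
        centre = u.mean(axis=0)
        centre /= np.linalg.norm(centre)
        max_angle = np.max(np.arccos(np.clip(u @ centre, -1, 1)))
        uk = unit_vectors(knots[:, 0], knots[:, 1])
        knot_angle = np.arccos(np.clip(uk @ centre, -1, 1))
        assert np.all(knot_angle <= max_angle + 1e-9)


class TestSplineBasis:
    def test_eta_closed_forms(self):
        # antipodal chord 2: eta = 4 log 2
        assert _eta(np.array([4.0]))[0] == pytest.approx(4 * np.log(2), rel=1e-12)
        assert _eta(np.array([0.0]))[0] == 0.0
        assert _eta(np.array([1.0]))[0] == 0.0  # c = 1: log term vanishes

    def test_basis_zero_at_own_knot(self, rng):
        knots = rng.uniform(0, 5, (8, 2))
        sb = spline_basis(knots, knots)
        np.testing.assert_allclose(np.diag(sb.basis), 0.0, atol=1e-12)
        # basis at knot j equals penalty[j, j] (both eta(0) = 0)
        np.testing.assert_allclose(np.diag(sb.basis), np.diag(sb.penalty), atol=1e-12)

    def test_identical_rows_for_identical_coords(self, rng):
        knots = rng.uniform(0, 5, (5, 2))
        coords = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 1.0]])
        sb = spline_basis(coords, knots)
        np.testing.assert_array_equal(sb.basis[0], sb.basis[1])

    def test_penalty_symmetric(self, rng):
        sb = spline_basis(rng.uniform(0, 5, (40, 2)), rng.uniform(0, 5, (12, 2)))
        np.testing.assert_allclose(sb.penalty, sb.penalty.T, atol=1e-15)
        clipped = _psd_clip(sb.penalty)
        assert np.min(np.linalg.eigvalsh(clipped)) >= -1e-8

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            spline_basis(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_no_knots_rejected(self):
        with pytest.raises(ValueError):
            spline_basis(np.array([[0.0, 0.0]]), np.empty((0, 2)))


class TestFitPenalizedLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(25), np.zeros(75)]
        design = _design_from_arrays(np.ones((100, 1)), y, np.zeros((100, 2)))
        model = fit_penalized_logistic(design)
        assert model.coefficients[0] == pytest.approx(np.log(25 / 75), abs=1e-8)
        assert model.edf == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_newton_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(80, 500)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        beta_true = rng.uniform(-1, 1, 4)
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(float)
        design = _design_from_arrays(X, y, np.zeros((n, 2)))
        model = fit_penalized_logistic(design)
        beta_oracle = newton_logistic(X, y)
        assert model.deviance == pytest.approx(logistic_deviance(X, y, beta_oracle), abs=1e-8)
        np.testing.assert_allclose(model.coefficients, beta_oracle, atol=1e-6)

    def test_huge_lambda_kills_spline(self, population):
        design = build_design(population, "physical")
        basis = spline_basis(design.coords, make_knots(design.coords, 10, seed=0))
        free = fit_penalized_logistic(design)
        pinned = fit_penalized_logistic(design, basis, lambda_grid=[1e12])
        w = pinned.coefficients[design.n_columns:]
        assert np.linalg.norm(w) < 1e-4
        np.testing.assert_allclose(pinned.coefficients[: design.n_columns],
                                   free.coefficients, atol=1e-3)
        assert pinned.deviance == pytest.approx(free.deviance, abs=1e-3)

    def test_single_class_rejected(self):
        design = _design_from_arrays(np.ones((20, 1)), np.ones(20), np.zeros((20, 2)))
        with pytest.raises(ValueError, match="single class"):
            fit_penalized_logistic(design)

    def test_separation_detected(self):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(float)
        design = _design_from_arrays(np.column_stack([np.ones(40), x]), y, np.zeros((40, 2)))
        with pytest.raises(SeparationError):
            fit_penalized_logistic(design)

    def test_fitted_probabilities_in_open_interval(self, population):
        design = build_design(population, "emotional")
        model = fit_penalized_logistic(design)
        assert np.all(model.fitted > 0) and np.all(model.fitted < 1)
        assert np.isfinite(model.aic)

    def test_edf_bounds_and_aic(self, population):
        design = build_design(population, "physical")
        basis = spline_basis(design.coords, make_knots(design.coords, 12, seed=1))
        model = fit_penalized_logistic(design, basis)
        assert design.n_columns - 1e-6 <= model.edf <= design.n_columns + 12 + 1e-6
        assert model.aic == pytest.approx(model.deviance + 2 * model.edf, rel=1e-12)

    def test_edf_matches_dense_eigen_oracle(self):
        # edf = sum of penalized-to-unpenalized eigenvalue ratios in the
        # whitened coordinate system, on a small instance
        rng = np.random.default_rng(3)
        n, k = 250, 10
        coords = np.column_stack([rng.uniform(0, 4, n), rng.uniform(0, 4, n)])
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = (rng.random(n) < 0.4).astype(float)
        design = _design_from_arrays(X, y, coords)
        basis = spline_basis(coords, make_knots(coords, k, seed=0))
        model = fit_penalized_logistic(design, basis, lambda_grid=[5.0])
        A = model.model_matrix
        w = model.fitted * (1 - model.fitted)
        AtWA = (A.T * w) @ A
        P = np.zeros((A.shape[1], A.shape[1]))
        P[3:, 3:] = 5.0 * _psd_clip(basis.penalty)
        # oracle: trace via generalized eigenvalues of (AtWA, AtWA + P)
        vals = np.linalg.eigvals(np.linalg.solve(AtWA + P, AtWA))
        assert model.edf == pytest.approx(float(np.real(vals).sum()), abs=1e-6)

    def test_penalty_limit_monotone_in_deviance(self, population):
        design = build_design(population, "physical")
        basis = spline_basis(design.coords, make_knots(design.coords, 10, seed=2))
        devs = [fit_penalized_logistic(design, basis, lambda_grid=[lam]).deviance
                for lam in (1e-2, 1e1, 1e4, 1e8)]
        assert all(b >= a - 1e-9 for a, b in zip(devs, devs[1:]))
        free = fit_penalized_logistic(design)
        assert devs[-1] <= free.deviance + 1e-3


class TestModelResiduals:
    def test_pearson_values(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        design = _design_from_arrays(np.ones((100, 1)), y, np.zeros((100, 2)))
        model = fit_penalized_logistic(design)
        r = model_residuals(model)
        mu = model.fitted[0]
        np.testing.assert_allclose(r[:30], (1 - mu) / np.sqrt(mu * (1 - mu)), rtol=1e-10)
        np.testing.assert_allclose(r[30:], -mu / np.sqrt(mu * (1 - mu)), rtol=1e-10)

    def test_elementwise_oracle(self, population):
        design = build_design(population, "controlling")
        model = fit_penalized_logistic(design)
        r = model_residuals(model)
        expected = np.array([(yi - pi) / np.sqrt(pi * (1 - pi))
                             for yi, pi in zip(model.y, model.fitted)])
        np.testing.assert_allclose(r, expected, atol=1e-10)

    def test_deviance_flag(self, population):
        design = build_design(population, "controlling")
        model = fit_penalized_logistic(design)
        rd = model_residuals(model, kind="deviance")
        assert rd.shape == model.y.shape
        assert np.all(np.sign(rd) == np.sign(model.y - model.fitted))
        with pytest.raises(ValueError):
            model_residuals(model, kind="anscombe")
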