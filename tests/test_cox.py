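import numpy as np
import pandas as pd
import pytest

from qgsurv import (
    CoxTimeVarying,
    GeneratorConfig,
    cox_loglik,
    fit_cox,
    make_cohort,
    natural_spline_basis,
    spline_curve,
)
from qgsurv.cox import CoxError, SingularInformationError
from qgsurv.pipeline import DEFAULT_COVARIATES

from tests.conftest import brute_partial_loglik, toy_cohort


def _arrays(cohort, cols):
    X = cohort.data[list(cols)].to_numpy(dtype=float)
    d = cohort.data
    return X, d["start"].to_numpy(), d["stop"].to_numpy(), d["event"].to_numpy()


class TestPartialLoglik:
    def test_null_model_is_minus_log_risk_set_size(self):
        # one event with 4 records at risk at its time: ll(0) = -ln 4
        rows = [
            ("a", 0.0, 2.0, 1, 1.0),
            ("b", 0.0, 3.0, 0, 2.0),
            ("c", 0.0, 2.5, 0, 3.0),
            ("d", 1.0, 2.2, 0, 4.0),
        ]
        c = toy_cohort(rows)
        X, start, stop, event = _arrays(c, ["pm25"])
        ll, _, _ = cox_loglik([0.0], X, start, stop, event)
        assert ll == pytest.approx(-np.log(4), abs=1e-14)

    def test_matches_brute_force_enumeration(self, three_subject_cohort):
        X, start, stop, event = _arrays(three_subject_cohort, ["pm25"])
        Xs = (X - X.mean()) / X.std()
        for ties in ("efron", "breslow"):
            ll, grad, info = cox_loglik([0.5], Xs, start, stop, event, ties=ties)
            expected = brute_partial_loglik([0.5], Xs, start, stop, event, ties=ties)
            assert ll == pytest.approx(expected, abs=1e-12)

    def test_gradient_and_hessian_match_finite_differences(self, three_subject_cohort):
        X, start, stop, event = _arrays(three_subject_cohort, ["pm25"])
        Xs = (X - X.mean()) / X.std()
        beta, h = 0.3, 1e-6
        ll, grad, info = cox_loglik([beta], Xs, start, stop, event)
        llp = brute_partial_loglik([beta + h], Xs, start, stop, event)
        llm = brute_partial_loglik([beta - h], Xs, start, stop, event)
        assert grad[0] == pytest.approx((llp - llm) / (2 * h), abs=1e-6)
        assert -info[0, 0] == pytest.approx((llp - 2 * ll + llm) / h**2, abs=1e-3)

    def test_efron_equals_breslow_without_ties(self, three_subject_cohort):
        X, start, stop, event = _arrays(three_subject_cohort, ["pm25"])
        le, ge, _ = cox_loglik([0.02], X, start, stop, event, ties="efron")
        lb, gb, _ = cox_loglik([0.02], X, start, stop, event, ties="breslow")
        assert le == pytest.approx(lb, abs=1e-14)
        assert ge == pytest.approx(gb, abs=1e-12)

    def test_efron_differs_from_breslow_with_ties(self):
        rows = [
            ("a", 0.0, 2.0, 1, 1.0),
            ("b", 0.0, 2.0, 1, 2.0),
            ("c", 0.0, 3.0, 0, 3.0),
            ("d", 0.0, 3.0, 0, 0.5),
        ]
        c = toy_cohort(rows)
        X, start, stop, event = _arrays(c, ["pm25"])
        le, *_ = cox_loglik([0.4], X, start, stop, event, ties="efron")
        lb, *_ = cox_loglik([0.4], X, start, stop, event, ties="breslow")
        assert le != pytest.approx(lb, abs=1e-10)
        assert le == pytest.approx(
            brute_partial_loglik([0.4], X, start, stop, event, "efron"), abs=1e-12
        )
        assert lb == pytest.approx(
            brute_partial_loglik([0.4], X, start, stop, event, "breslow"), abs=1e-12
        )

    def test_zero_events_rejected(self):
        rows = [("a", 0.0, 1.0, 0, 1.0), ("b", 0.0, 2.0, 0, 2.0)]
        c = toy_cohort(rows)
        X, start, stop, event = _arrays(c, ["pm25"])
        with pytest.raises(CoxError, match="no events"):
            cox_loglik([0.0], X, start, stop, event)

    def test_concavity_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            n = 30
            start = np.zeros(n)
            stop = rng.uniform(0.5, 3.0, n)
            event = rng.integers(0, 2, n)
            event[0] = 1
            X = rng.normal(size=(n, 2))
            beta = rng.normal(scale=0.5, size=2)
            _, _, info = cox_loglik(beta, X, start, stop, event)
            assert np.linalg.eigvalsh(info).min() >= -1e-10


class TestFitCox:
    def test_constant_exposure_singular(self):
        rows = [("a", 0.0, 1.0, 1, 5.0), ("b", 0.0, 2.0, 1, 5.0), ("c", 0.0, 2.5, 0, 5.0)]
        c = toy_cohort(rows)
        with pytest.raises(SingularInformationError, match="pm25"):
            fit_cox(c, "pm25", quantize_exposure=False)

    def test_one_dimensional_grid_search_oracle(self):
        rows = [
            ("a", 0.0, 1.0, 0, 0.2), ("a", 1.0, 2.1, 1, 0.9),
            ("b", 0.0, 1.4, 0, -0.5), ("b", 1.4, 3.0, 1, 0.1),
            ("c", 0.0, 2.4, 0, -1.2), ("d", 0.5, 2.8, 1, 1.5),
            ("e", 0.0, 3.2, 0, -0.3), ("f", 1.0, 3.5, 0, 0.6),
        ]
        c = toy_cohort(rows)
        X, start, stop, event = _arrays(c, ["pm25"])
        grid = np.linspace(-3, 3, 60001)
        lls = [brute_partial_loglik([b], X, start, stop, event) for b in grid]
        b_grid = grid[int(np.argmax(lls))]
        fit = fit_cox(c, "pm25", quantize_exposure=False)
        assert fit.coef_[0] == pytest.approx(b_grid, abs=1e-4)
        assert fit.converged_

    def test_agrees_with_lifelines_on_random_cohorts(self):
        from lifelines import CoxTimeVaryingFitter

        from qgsurv.cohort import design_matrix

        max_diff = 0.0
        for seed in range(20):
            cfg = GeneratorConfig(
                n_subjects=150,
                true_log_hr={"pm25": 0.3, "o3": -0.1},
                target_incidence=0.25,
            )
            cohort, _ = make_cohort(cfg, seed=seed)
            X = design_matrix(cohort, ["pm25", "o3", "sex"])
            mine = CoxTimeVarying().fit(X, cohort.data[["start", "stop", "event"]])
            df = pd.concat(
                [X, cohort.data[["start", "stop", "event", "subject_id"]]], axis=1
            )
            ctv = CoxTimeVaryingFitter()
            ctv.fit(df, id_col="subject_id", start_col="start", stop_col="stop",
                    event_col="event")
            max_diff = max(max_diff, np.abs(ctv.params_.to_numpy() - mine.coef_).max())
        assert max_diff < 1e-5

    def test_score_small_at_optimum(self, small_sim_cohort):
        cohort, _ = small_sim_cohort
        fit = fit_cox(cohort, "pm25", ["sex", "age_group"])
        from qgsurv.cohort import design_matrix, quantize

        work, _ = quantize(cohort, "pm25")
        X = design_matrix(work, ["pm25_q", "sex", "age_group"])
        d = work.data
        _, grad, _ = cox_loglik(
            fit.coef_, X.to_numpy(), d["start"].to_numpy(), d["stop"].to_numpy(),
            d["event"].to_numpy(),
        )
        assert np.max(np.abs(grad)) < 1e-6
        assert np.allclose(fit.covariance_, fit.covariance_.T, atol=1e-12)
        assert (np.diag(fit.covariance_) >= 0).all()

    def test_sklearn_params_clone(self):
        from sklearn.base import clone

        est = CoxTimeVarying(ties="breslow", tol=1e-6)
        est2 = clone(est)
        assert est2.get_params() == {"ties": "breslow", "tol": 1e-6, "max_iter": 50}


class TestWaldCoverage:
    def test_nominal_95_coverage_between_90_and_99(self):
        true_beta = np.log(1.18)
        covered = 0
        n_sims = 200
        for seed in range(n_sims):
            cfg = GeneratorConfig(n_subjects=2000, true_log_hr={"pm25": true_beta})
            cohort, _ = make_cohort(cfg, seed=seed)
            fit = fit_cox(cohort, "pm25", [])
            se = fit.standard_errors_[0]
            lo, hi = fit.coef_[0] - 1.96 * se, fit.coef_[0] + 1.96 * se
            covered += lo <= true_beta <= hi
        assert 0.90 <= covered / n_sims <= 0.99


class TestNaturalSpline:
    def test_basis_spans_natural_spline_space(self):
        # independent construction: cubic B-spline space restricted to zero
        # second derivative at the boundary knots via null-space projection
        from scipy.interpolate import BSpline

        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 10, 400))
        interior = np.array([4.0, 6.0])
        boundary = (1.0, 9.0)
        B = natural_spline_basis(x, interior, boundary)
        assert B.shape == (400, 3)

        knots = np.concatenate(
            ([boundary[0]] * 4, interior, [boundary[1]] * 4)
        )
        nb = len(knots) - 4
        basis = [
            BSpline(knots, np.eye(nb)[i], 3, extrapolate=True) for i in range(nb)
        ]

        def eval_all(pts):
            return np.column_stack([b(pts) for b in basis])

        # constraint: second derivative 0 at both boundary knots
        d2 = np.column_stack(
            [b.derivative(2)(np.array(boundary)) for b in basis]
        )  # (2, nb)
        from scipy.linalg import null_space

        N = null_space(d2)  # (nb, nb-2) coefficient space of natural splines
        inside = (x >= boundary[0]) & (x <= boundary[1])
        O = eval_all(x[inside]) @ N  # oracle basis on interior points
        # each package basis column must lie in the oracle span (plus intercept)
        A = np.column_stack([np.ones(O.shape[0]), O])
        proj, *_ = np.linalg.lstsq(A, B[inside], rcond=None)
        resid = B[inside] - A @ proj
        assert np.max(np.abs(resid)) < 1e-10

    def test_linear_beyond_boundary_knots(self):
        interior = np.array([4.0, 6.0])
        B = natural_spline_basis(np.array([9.5, 10.0, 10.5, 11.0]), interior, (1.0, 9.0))
        slopes = np.diff(B, axis=0) / 0.5
        assert np.allclose(slopes[0], slopes[1], atol=1e-10)
        assert np.allclose(slopes[1], slopes[2], atol=1e-10)

    def test_curve_zero_at_reference(self, small_sim_cohort):
        cohort, _ = small_sim_cohort
        curve = spline_curve(cohort, "pm25", ["sex"], grid=np.array([40.0, 42.0]),
                             reference=42.0)
        assert curve.log_hr[1] == pytest.approx(0.0, abs=1e-14)
        assert curve.se[1] == pytest.approx(0.0, abs=1e-12)

    def test_linear_truth_within_pointwise_ci(self):
        # data generated with a linear log-hazard in the raw exposure: the
        # fitted spline should rarely exclude the best linear fit
        hits, total = 0, 0
        for seed in range(5):
            cfg = GeneratorConfig(
                n_subjects=2500, true_log_hr={"pm25": 0.15}, target_incidence=0.12
            )
            cohort, _ = make_cohort(cfg, seed=seed)
            curve = spline_curve(cohort, "pm25", [], grid=20)
            # best linear approximation to the fitted curve
            A = np.column_stack([np.ones(20), curve.grid])
            coef, *_ = np.linalg.lstsq(A, curve.log_hr, rcond=None)
            lin = A @ coef
            ok = (lin >= curve.ci_low) & (lin <= curve.ci_high)
            hits += ok.sum()
            total += ok.size
        assert hits / total >= 0.85
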