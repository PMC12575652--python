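"""Penalized selection: solver oracles, CV tuning, composite construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from multipgs import (
    LabeledScores,
    PenaltyGrid,
    ScoreMatrix,
    build_composite_mps,
    cv_select,
    fit_penalized_logistic,
    standardize_scores,
)
from multipgs.mps_selection import _objective, lambda_max


def _design(n, K, seed, beta=None):
    """Standardized score matrix, two covariates, logistic outcome."""
    rng = np.random.default_rng(seed)
    Xs = rng.normal(size=(n, K))
    Xs = (Xs - Xs.mean(0)) / Xs.std(0, ddof=1)
    cov = pd.DataFrame({"age": rng.normal(size=n), "male": rng.integers(0, 2, n).astype(float)})
    if beta is None:
        beta = np.zeros(K)
    eta = -1.0 + Xs @ beta + 0.3 * cov["age"].to_numpy() + 0.2 * cov["male"].to_numpy()
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
    sm = ScoreMatrix([f"i{k}" for k in range(n)], [f"P{j}" for j in range(K)], Xs)
    return sm, cov, y


def _stack(sm, cov):
    return np.column_stack([cov.to_numpy(), sm.values])


def _full_objective(params, X, y, pen_mask, alpha, lam):
    return _objective(X @ params[1:] + params[0], y, params[1:], pen_mask, alpha, lam)


class TestFitPenalizedLogistic:
    def test_infinite_penalty_recovers_covariate_only_fit(self):
        import statsmodels.api as sm_api

        sm, cov, y = _design(400, 5, seed=1, beta=np.array([0.5, -0.3, 0, 0, 0.2]))
        fit = fit_penalized_logistic(sm, cov, y, alpha=0.75, lam=1e6)
        assert all(v == 0 for v in fit.prs_coefficients.values())
        ref = sm_api.Logit(y, sm_api.add_constant(cov)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params["const"], abs=1e-6)
        for name in ("age", "male"):
            assert fit.covariate_coefficients[name] == pytest.approx(ref.params[name], abs=1e-6)

    def test_unpenalized_fit_matches_generic_optimizer(self):
        sm, cov, y = _design(300, 5, seed=2, beta=np.array([0.4, -0.2, 0.1, 0, 0]))
        fit = fit_penalized_logistic(sm, cov, y, alpha=0.5, lam=0.0)
        X = _stack(sm, cov)
        pen = np.r_[np.zeros(2, bool), np.ones(5, bool)]
        res = minimize(
            _full_objective, np.zeros(8), args=(X, y.astype(float), pen, 0.5, 0.0),
            method="BFGS", options={"gtol": 1e-10, "maxiter": 2000},
        )
        got = np.r_[
            fit.intercept,
            [fit.covariate_coefficients[c] for c in cov.columns],
            [fit.prs_coefficients[p] for p in sm.score_ids],
        ]
        np.testing.assert_allclose(got, res.x, atol=1e-5)

    def test_ridge_point_matches_independent_objective_minimizer(self):
        sm, cov, y = _design(50, 3, seed=3, beta=np.array([0.6, 0, -0.4]))
        lam = 0.05
        fit = fit_penalized_logistic(sm, cov, y, alpha=0.0, lam=lam)
        X = _stack(sm, cov)
        pen = np.r_[np.zeros(2, bool), np.ones(3, bool)]
        res = minimize(
            _full_objective, np.zeros(6), args=(X, y.astype(float), pen, 0.0, lam),
            method="BFGS", options={"gtol": 1e-12, "maxiter": 5000},
        )
        got = np.r_[
            fit.intercept,
            [fit.covariate_coefficients[c] for c in cov.columns],
            [fit.prs_coefficients[p] for p in sm.score_ids],
        ]
        np.testing.assert_allclose(got, res.x, atol=1e-5)

    def test_objective_no_worse_than_zero_score_solution(self):
        sm, cov, y = _design(200, 4, seed=4, beta=np.array([0.5, 0, 0, 0]))
        alpha, lam = 0.5, 0.01
        fit = fit_penalized_logistic(sm, cov, y, alpha, lam)
        zero = fit_penalized_logistic(sm, cov, y, alpha, 1e6)
        X = _stack(sm, cov)
        pen = np.r_[np.zeros(2, bool), np.ones(4, bool)]

        def obj(f):
            params = np.r_[
                f.intercept,
                [f.covariate_coefficients[c] for c in cov.columns],
                [f.prs_coefficients[p] for p in sm.score_ids],
            ]
            return _full_objective(params, X, y.astype(float), pen, alpha, lam)

        assert obj(fit) <= obj(zero) + 1e-12

    def test_lambda_max_zeroes_everything_at_alpha_one(self):
        sm, cov, y = _design(300, 5, seed=5, beta=np.array([0.4, 0.3, 0, 0, 0]))
        lmax = lambda_max(sm.values, cov.to_numpy(), y)
        at_max = fit_penalized_logistic(sm, cov, y, alpha=1.0, lam=lmax * 1.0001)
        assert all(v == 0 for v in at_max.prs_coefficients.values())
        below = fit_penalized_logistic(sm, cov, y, alpha=1.0, lam=lmax * 0.5)
        assert any(v != 0 for v in below.prs_coefficients.values())

    def test_lasso_path_sparsity_monotone_in_lambda(self):
        sm, cov, y = _design(150, 6, seed=6, beta=np.array([0.6, 0.4, 0.2, 0, 0, 0]))
        lmax = lambda_max(sm.values, cov.to_numpy(), y)
        counts = []
        for lam in np.geomspace(lmax, lmax * 1e-3, 12):
            fit = fit_penalized_logistic(sm, cov, y, alpha=1.0, lam=lam)
            counts.append(sum(v != 0 for v in fit.prs_coefficients.values()))
        assert counts == sorted(counts)

    def test_both_classes_required(self):
        sm, cov, _ = _design(50, 2, seed=7)
        with pytest.raises(ValueError, match="both classes"):
            fit_penalized_logistic(sm, cov, np.ones(50, int), 0.5, 0.1)


class TestCvSelect:
    def _conf(self, n, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"sex": rng.integers(0, 2, n)})

    def test_single_grid_point_equals_full_data_fit(self):
        sm, cov, y = _design(200, 3, seed=8, beta=np.array([0.5, 0, 0]))
        conf = self._conf(200, 8)
        grid = PenaltyGrid(alphas=(0.5,), lambdas=(0.05,), n_folds=4)
        via_cv = cv_select(sm, cov, y, conf, grid, seed=1)
        direct = fit_penalized_logistic(sm, cov, y, 0.5, 0.05)
        assert len(via_cv.cv_table) == 1
        assert via_cv.prs_coefficients == pytest.approx(direct.prs_coefficients)

    def test_bit_reproducible_given_seed(self):
        sm, cov, y = _design(300, 4, seed=9, beta=np.array([0.5, 0.3, 0, 0]))
        conf = self._conf(300, 9)
        grid = PenaltyGrid(alphas=(0.25, 1.0), n_lambdas=6, n_folds=4)
        f1 = cv_select(sm, cov, y, conf, grid, seed=3)
        f2 = cv_select(sm, cov, y, conf, grid, seed=3)
        assert f1.alpha == f2.alpha and f1.lam == f2.lam
        assert f1.prs_coefficients == f2.prs_coefficients
        pd.testing.assert_frame_equal(f1.cv_table, f2.cv_table)

    def test_chosen_point_maximizes_mean_cv_auc(self):
        sm, cov, y = _design(300, 4, seed=10, beta=np.array([0.5, 0.3, 0, 0]))
        grid = PenaltyGrid(alphas=(0.0, 1.0), n_lambdas=5, n_folds=4)
        fit = cv_select(sm, cov, y, self._conf(300, 10), grid, seed=4)
        table = fit.cv_table
        chosen = table[(table["alpha"] == fit.alpha) & (table["lambda"] == fit.lam)]
        assert chosen["mean_cv_auc"].iloc[0] == table["mean_cv_auc"].max()

    def test_null_scores_yield_near_chance_cv_auc(self):
        # no signal: the best grid point's mean CV adjusted AUC stays near 0.5
        best = []
        for rep in range(20):
            sm, cov, y = _design(400, 5, seed=100 + rep)  # beta = 0
            grid = PenaltyGrid(alphas=(0.5,), n_lambdas=5, n_folds=4)
            fit = cv_select(sm, cov, y, self._conf(400, rep), grid, seed=rep)
            best.append(fit.cv_table["mean_cv_auc"].max())
        assert np.mean(best) <= 0.55

    def test_pleiotropic_traits_selected_noise_traits_rarely(self):
        """Selection-recovery simulation at the generator's default scale
        (reduced grid and sim count for runtime): traits sharing causal
        variants with the outcome are selected essentially always; pure-noise
        traits enter far less often. The CV-maximum rule deliberately tunes
        for discrimination, not sparsity, so occasional small-coefficient
        noise components are expected — the guarantee is the contrast."""
        from multipgs import SimulationConfig, simulate_cohort
        from multipgs.pipeline import _confounder_frame, _covariate_frame
        from multipgs.risk_models import ADVANCED_NEOPLASIA, define_outcome

        hits = np.zeros(10)
        n_sims = 10
        for rep in range(n_sims):
            cfg = SimulationConfig(seed=700 + rep)
            geno, truth, phen = simulate_cohort(cfg)
            scores = geno.dosages @ truth.published_trait_weights.T
            sm = standardize_scores(
                ScoreMatrix(geno.individual_ids, [f"T{k}" for k in range(10)], scores)
            )
            labels, _ = define_outcome(phen, ADVANCED_NEOPLASIA)
            fit = cv_select(
                sm,
                _covariate_frame(phen, with_platform=True),
                labels,
                _confounder_frame(phen, ("age_decade", "sex", "platform")),
                PenaltyGrid(alphas=(0.5, 1.0), n_lambdas=8, n_folds=4),
                seed=rep,
            )
            nz = fit.nonzero()
            hits += [f"T{k}" in nz for k in range(10)]
        rates = hits / n_sims
        assert all(rates[:3] >= 0.8), f"pleiotropic selection rates too low: {rates[:3]}"
        assert all(rates[3:] <= 0.7), f"a noise trait was selected too often: {rates[3:]}"
        assert rates[3:].mean() <= 0.5, f"mean noise selection rate too high: {rates[3:]}"


class TestCompositeMps:
    def test_single_component_equals_that_score(self):
        rng = np.random.default_rng(11)
        sm = standardize_scores(
            ScoreMatrix([f"i{k}" for k in range(30)], ["A", "B"], rng.normal(size=(30, 2)))
        )
        fit = fit_penalized_logistic(sm, None, (rng.uniform(size=30) < 0.5).astype(int), 1.0, 1e6)
        fit.prs_coefficients = {"A": 1.0, "B": 0.0}
        mps, comp = build_composite_mps(fit, sm)
        col = sm.column("A")
        np.testing.assert_allclose(mps, (col - col.mean()) / col.std(ddof=1), atol=1e-12)
        assert comp.components == {"A": 1.0}

    def test_two_component_hand_computed_combination(self):
        sm = ScoreMatrix(
            ["a", "b", "c", "d"], ["A", "B"],
            np.array([[1.0, 2.0], [2.0, 0.0], [3.0, 1.0], [0.0, -1.0]]),
        )
        fit = fit_penalized_logistic(
            sm, None, np.array([0, 1, 0, 1]), 1.0, 1e6
        )
        fit.prs_coefficients = {"A": 0.5, "B": -2.0}
        mps, comp = build_composite_mps(fit, sm)
        raw = 0.5 * sm.values[:, 0] - 2.0 * sm.values[:, 1]
        np.testing.assert_allclose(mps, (raw - raw.mean()) / raw.std(ddof=1), atol=1e-12)
        np.testing.assert_allclose(comp.apply(sm), mps, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(20, 2))
        ids = [f"i{k}" for k in range(20)]
        sm = ScoreMatrix(ids, ["A", "B"], values)
        fit = fit_penalized_logistic(sm, None, rng.integers(0, 2, 20), 1.0, 1e6)
        fit.prs_coefficients = {"A": 0.7, "B": 0.3}
        mps, _ = build_composite_mps(fit, sm)
        perm = rng.permutation(20)
        sm_p = ScoreMatrix([ids[i] for i in perm], ["A", "B"], values[perm])
        mps_p, _ = build_composite_mps(fit, sm_p)
        np.testing.assert_allclose(mps_p, mps[perm], atol=1e-12)

    def test_missing_component_column_named(self):
        sm = ScoreMatrix(["a", "b", "c"], ["A"], np.array([[1.0], [2.0], [0.5]]))
        fit = fit_penalized_logistic(sm, None, np.array([0, 1, 1]), 1.0, 1e6)
        fit.prs_coefficients = {"ZZZ": 1.0}
        with pytest.raises(KeyError, match="ZZZ"):
            build_composite_mps(fit, sm)

    def test_no_selection_is_error(self):
        sm = ScoreMatrix(["a", "b", "c"], ["A"], np.array([[1.0], [2.0], [0.5]]))
        fit = fit_penalized_logistic(sm, None, np.array([0, 1, 1]), 1.0, 1e6)
        with pytest.raises(ValueError, match="no scores"):
            build_composite_mps(fit, sm)
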