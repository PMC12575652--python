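"""Penalized multi-score selection and composite score construction.

Many published polygenic scores are mutually correlated (shared GWAS
signal, pleiotropy), so picking the informative ones is a variable
selection problem. This module fits an elastic-net-penalized logistic
regression of case status on the full standardized score matrix, with
epidemiological covariates (age, sex, platform) left unpenalized so the
penalty budget is spent on scores only. The mixing parameter alpha spans
ridge (0) to lasso (1); the pair (alpha, lambda) is tuned by stratified
k-fold cross-validation maximizing the confounder-adjusted AUC of the
held-out score-only linear predictor. The selected scores and their
refit coefficients define a single composite score (the MPS).

The solver is glmnet-style cyclic coordinate descent on the IRLS
quadratic approximation; its contract is the penalized objective

    (1/n) sum_i [log(1 + exp(eta_i)) - y_i eta_i]
        + lambda * sum_{j in scores} [alpha |b_j| + (1-alpha) b_j^2 / 2]

with intercept and covariates unpenalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cadj_auc import LabeledScores, confounder_adjusted_auc
from .prs_engine import ScoreMatrix

__all__ = [
    "PenaltyGrid",
    "PenalizedFit",
    "CompositeMPS",
    "ConvergenceError",
    "fit_penalized_logistic",
    "cv_select",
    "build_composite_mps",
    "lambda_max",
]

logger = logging.getLogger(__name__)

SEPARATION_COEF = 30.0  # |coef| beyond this on standardized scale smells of separation


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, objective_trace: list[float]):
        super().__init__(message)
        self.objective_trace = objective_trace


@dataclass
class PenaltyGrid:
    """Search grid for the elastic-net tuning parameters.

    ``lambdas=None`` means: derive a 50-point log-spaced path from the
    data, from the smallest lambda that zeroes every score coefficient at
    alpha=1 down to 1e-4 of it.
    """

    alphas: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    lambdas: tuple[float, ...] | None = None
    n_folds: int = 10
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-4

    def __post_init__(self) -> None:
        self.alphas = tuple(sorted(self.alphas))
        if any(a < 0 or a > 1 for a in self.alphas):
            raise ValueError("alphas must lie in [0, 1]")
        if self.lambdas is not None:
            self.lambdas = tuple(sorted(self.lambdas, reverse=True))
            if any(l <= 0 for l in self.lambdas):
                raise ValueError("lambdas must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class PenalizedFit:
    alpha: float
    lam: float
    prs_coefficients: dict[str, float]
    covariate_coefficients: dict[str, float]
    intercept: float
    cv_table: pd.DataFrame | None = None
    n_iter: int = 0

    def nonzero(self) -> dict[str, float]:
        return {k: v for k, v in self.prs_coefficients.items() if v != 0.0}


@dataclass
class CompositeMPS:
    """Linear combination of selected scores plus post-hoc standardization."""

    components: dict[str, float]
    mean: float
    sd: float

    def apply(self, scores: ScoreMatrix) -> np.ndarray:
        """Composite value on new individuals using the recorded moments."""
        missing = [k for k in self.components if k not in scores.score_ids]
        if missing:
            raise KeyError(f"score matrix lacks composite component(s): {missing}")
        raw = np.zeros(len(scores.individual_ids))
        for pgs_id, coef in self.components.items():
            raw += coef * scores.column(pgs_id)
        return (raw - self.mean) / self.sd


# ---------------------------------------------------------------------------
# Core solver


def _objective(
    eta: np.ndarray, y: np.ndarray, beta: np.ndarray, pen_mask: np.ndarray,
    alpha: float, lam: float,
) -> float:
    nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    bp = beta[pen_mask]
    return nll + lam * float(alpha * np.abs(bp).sum() + (1 - alpha) * 0.5 * (bp**2).sum())


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _enet_logistic(
    X: np.ndarray,
    y: np.ndarray,
    pen_mask: np.ndarray,
    alpha: float,
    lam: float,
    coef0: np.ndarray | None = None,
    intercept0: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[float, np.ndarray, int]:
    """Coordinate-descent elastic-net logistic with per-column penalty mask.

    Returns (intercept, coefficients, n_outer_iterations). Converges when
    the penalized objective changes by less than ``tol`` (relative);
    raises :class:`ConvergenceError` otherwise.
    """
    n, p = X.shape
    beta = np.zeros(p) if coef0 is None else coef0.astype(float).copy()
    b0 = float(intercept0)
    eta = X @ beta + b0
    trace = [_objective(eta, y, beta, pen_mask, alpha, lam)]
    la = lam * alpha
    lb = lam * (1.0 - alpha)
    for it in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-5, None)
        r = (y - mu) / w  # working residual z - eta at current coefficients
        denom = (w @ (X * X)) / n
        wsum = w.sum()
        for _ in range(100):
            max_delta = 0.0
            d0 = (w @ r) / wsum
            if d0 != 0.0:
                b0 += d0
                r -= d0
                max_delta = abs(d0)
            wr = w * r
            for j in range(p):
                xj = X[:, j]
                rho = (xj @ wr) / n + denom[j] * beta[j]
                if pen_mask[j]:
                    new = _soft(rho, la) / (denom[j] + lb)
                else:
                    new = rho / denom[j]
                d = new - beta[j]
                if d != 0.0:
                    beta[j] = new
                    r -= xj * d
                    wr -= (w * xj) * d
                    max_delta = max(max_delta, abs(d))
            if max_delta < 1e-11:
                break
        eta = X @ beta + b0
        obj = _objective(eta, y, beta, pen_mask, alpha, lam)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(1.0, abs(obj)):
            if np.abs(beta).max(initial=0.0) > SEPARATION_COEF:
                warnings.warn(
                    "coefficient magnitude suggests (quasi-)separation", stacklevel=2
                )
            return b0, beta, it + 1
    raise ConvergenceError(
        f"penalized logistic failed to converge in {max_iter} iterations", trace
    )


def lambda_max(
    scores: np.ndarray, covariates: np.ndarray, labels: np.ndarray
) -> float:
    """Smallest lambda (at alpha=1) that zeroes every score coefficient.

    Computed from the gradient of the log-likelihood at the covariate-only
    fit: max_j |(1/n) x_j' (y - p_hat)| over score columns.
    """
    n = len(labels)
    pen = np.zeros(covariates.shape[1], dtype=bool)
    b0, gamma, _ = _enet_logistic(covariates, labels.astype(float), pen, 0.0, 0.0)
    mu = 1.0 / (1.0 + np.exp(-(covariates @ gamma + b0)))
    grad = scores.T @ (labels - mu) / n
    return float(np.abs(grad).max())


def _as_arrays(
    scores: ScoreMatrix | np.ndarray, covariates: np.ndarray | pd.DataFrame | None
) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    if isinstance(scores, ScoreMatrix):
        Xs, score_ids = scores.values, list(scores.score_ids)
    else:
        Xs = np.asarray(scores, dtype=float)
        score_ids = [f"score_{k}" for k in range(Xs.shape[1])]
    if covariates is None:
        Xc = np.empty((Xs.shape[0], 0))
        cov_names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        Xc = covariates.to_numpy(dtype=float)
        cov_names = [str(c) for c in covariates.columns]
    else:
        Xc = np.asarray(covariates, dtype=float)
        cov_names = [f"cov_{k}" for k in range(Xc.shape[1])]
    return Xs, score_ids, Xc, cov_names


def fit_penalized_logistic(
    scores: ScoreMatrix | np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None,
    labels: np.ndarray,
    alpha: float,
    lam: float,
) -> PenalizedFit:
    """Single-point elastic-net logistic fit; scores penalized, covariates not.

    ``scores`` should be standardized (mean 0, SD 1) so the shared lambda
    treats every score on the same scale.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes, coded 0/1")
    Xs, score_ids, Xc, cov_names = _as_arrays(scores, covariates)
    X = np.column_stack([Xc, Xs]) if Xc.size else Xs
    pen = np.concatenate([np.zeros(Xc.shape[1], bool), np.ones(Xs.shape[1], bool)])
    b0, beta, n_iter = _enet_logistic(X, y, pen, alpha, lam)
    nc = Xc.shape[1]
    return PenalizedFit(
        alpha=alpha,
        lam=lam,
        prs_coefficients=dict(zip(score_ids, beta[nc:])),
        covariate_coefficients=dict(zip(cov_names, beta[:nc])),
        intercept=b0,
        n_iter=n_iter,
    )


def _fit_path(
    X: np.ndarray,
    y: np.ndarray,
    pen: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
) -> list[tuple[float, np.ndarray]]:
    """Warm-started fits along a descending lambda path at fixed alpha."""
    out = []
    b0, beta = 0.0, None
    for lam in lambdas:
        b0, beta, _ = _enet_logistic(X, y, pen, alpha, lam, coef0=beta, intercept0=b0)
        out.append((b0, beta.copy()))
    return out


def cv_select(
    scores: ScoreMatrix,
    covariates: pd.DataFrame | np.ndarray | None,
    labels: np.ndarray,
    confounders: pd.DataFrame,
    grid: PenaltyGrid | None = None,
    seed: int | None = None,
    auc_method: str = "strata",
) -> PenalizedFit:
    """Grid search (alpha, lambda) by stratified k-fold CV on adjusted AUC.

    Folds are assigned by a seeded label-stratified shuffle. For each grid
    point the model is fit on k-1 folds and the held-out individuals are
    scored with the score-only linear predictor (covariates deliberately
    excluded: they enter the adjusted AUC as confounders instead, so the
    metric credits the scores alone). The grid point with the highest mean
    fold AUC wins; ties prefer larger lambda, then larger alpha (sparser
    models). The model is then refit on the full data at the winner.
    """
    from sklearn.model_selection import StratifiedKFold

    if grid is None:
        grid = PenaltyGrid()
    y = np.asarray(labels, dtype=float)
    Xs, score_ids, Xc, cov_names = _as_arrays(scores, covariates)
    X = np.column_stack([Xc, Xs]) if Xc.size else Xs
    pen = np.concatenate([np.zeros(Xc.shape[1], bool), np.ones(Xs.shape[1], bool)])
    nc = Xc.shape[1]

    if grid.lambdas is None:
        lmax = lambda_max(Xs, Xc if Xc.size else np.empty((len(y), 0)), y)
        lambdas = np.geomspace(lmax, lmax * grid.lambda_min_ratio, grid.n_lambdas)
    else:
        lambdas = np.asarray(grid.lambdas, dtype=float)

    skf = StratifiedKFold(n_splits=grid.n_folds, shuffle=True, random_state=seed)
    fold_aucs = np.zeros((grid.n_folds, len(grid.alphas), len(lambdas)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        conf_te = confounders.iloc[te]
        for a, alpha in enumerate(grid.alphas):
            path = _fit_path(X[tr], y[tr], pen, alpha, lambdas)
            for l, (_, beta) in enumerate(path):
                held = Xs[te] @ beta[nc:]
                data = LabeledScores(held, y[te].astype(int), conf_te)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fold_aucs[f, a, l] = confounder_adjusted_auc(data, auc_method).auc

    mean_auc = fold_aucs.mean(axis=0)
    sd_auc = fold_aucs.std(axis=0, ddof=1)
    rows = [
        {
            "alpha": alpha,
            "lambda": lam,
            "mean_cv_auc": mean_auc[a, l],
            "sd_cv_auc": sd_auc[a, l],
        }
        for a, alpha in enumerate(grid.alphas)
        for l, lam in enumerate(lambdas)
    ]
    cv_table = pd.DataFrame(rows)

    # argmax with ties broken toward larger lambda, then larger alpha
    best = None
    for a, alpha in enumerate(grid.alphas):
        for l, lam in enumerate(lambdas):
            key = (mean_auc[a, l], lam, alpha)
            if best is None or key > best[0]:
                best = (key, a, l)
    _, a_best, l_best = best

    fit = fit_penalized_logistic(
        scores if isinstance(scores, ScoreMatrix) else Xs,
        covariates,
        y.astype(int),
        grid.alphas[a_best],
        float(lambdas[l_best]),
    )
    fit.cv_table = cv_table
    logger.info(
        "cv_select: alpha=%.3g lambda=%.4g mean CV AUC=%.4f (%d nonzero scores)",
        fit.alpha, fit.lam, mean_auc[a_best, l_best], len(fit.nonzero()),
    )
    return fit


def build_composite_mps(
    fit: PenalizedFit, scores: ScoreMatrix
) -> tuple[np.ndarray, CompositeMPS]:
    """Combine the selected scores into one standardized composite.

    MPS_i = sum_k c_k * score_ik over the nonzero coefficients, then
    centred and scaled to SD 1; the raw-combination moments are recorded
    so held-out samples get the identical affine transform.
    """
    components = fit.nonzero()
    if not components:
        raise ValueError("penalized fit selected no scores; cannot build a composite")
    missing = [k for k in components if k not in scores.score_ids]
    if missing:
        raise KeyError(f"score matrix lacks composite component(s): {missing}")
    raw = np.zeros(len(scores.individual_ids))
    for pgs_id, coef in components.items():
        raw += coef * scores.column(pgs_id)
    mean = float(raw.mean())
    sd = float(raw.std(ddof=1))
    if sd == 0:
        raise ValueError("composite has zero variance")
    mps = CompositeMPS(components=components, mean=mean, sd=sd)
    return (raw - mean) / sd, mps
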