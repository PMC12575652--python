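"""Confounder-adjusted AUC, bootstrap uncertainty, and paired AUC comparison.

The discrimination of a risk score is measured by the area under the ROC
curve, estimated by the Mann-Whitney statistic. To isolate the score's own
contribution from confounders that predict the outcome anyway (age, sex,
genotyping platform), cases are reweighted so that their confounder
distribution matches that of the controls; the weighted Mann-Whitney
statistic is then the confounder-adjusted AUC. Two weight engines are
provided: exact strata ratios (categorical confounders) and inverse-odds
weights from a logistic model (continuous confounders allowed).

Uncertainty comes from a nonparametric bootstrap over individuals; model
comparisons reuse the same resample in both models (paired bootstrap) and
test the AUC difference with a normal z-statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LabeledScores",
    "AUCResult",
    "AUCComparison",
    "empirical_auc",
    "confounder_weights",
    "confounder_adjusted_auc",
    "bootstrap_auc",
    "compare_auc_bootstrap",
]

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 1000


@dataclass
class LabeledScores:
    """Per-individual risk scores with case/control labels and confounders.

    ``confounders`` is a DataFrame (may have zero columns for an unadjusted
    analysis); for the ``strata`` weight engine every column must be
    categorical/discrete (bin age beforehand).
    """

    scores: np.ndarray
    labels: np.ndarray
    confounders: pd.DataFrame

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.scores) == len(self.labels) == len(self.confounders)):
            raise ValueError("scores, labels and confounders must have equal length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if self.labels.sum() == 0 or self.labels.sum() == len(self.labels):
            raise ValueError("need at least one case and one control")

    def __len__(self) -> int:
        return len(self.scores)

    def take(self, idx: np.ndarray) -> "LabeledScores":
        return LabeledScores(
            self.scores[idx], self.labels[idx], self.confounders.iloc[idx]
        )


@dataclass
class AUCResult:
    auc: float
    se: float = 0.0
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    n_redraws: int = 0
    n_dropped_cases: int = 0


@dataclass
class AUCComparison:
    """Paired bootstrap comparison of two scores on the same individuals."""

    delta: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p_two_sided: float
    auc_a: AUCResult | None = None
    auc_b: AUCResult | None = None


def _weighted_auc(
    case_scores: np.ndarray, control_scores: np.ndarray, case_weights: np.ndarray | None
) -> float:
    """Weighted Mann-Whitney AUC via sorted-control binary search.

    Equals the O(n1*n0) double loop sum_i sum_j w_i (1[s_i>s_j] + .5 1[s_i=s_j])
    normalised by (sum w_i) * n0; ties contribute one half.
    """
    n0 = control_scores.size
    cs = np.sort(control_scores)
    lo = np.searchsorted(cs, case_scores, side="left")
    hi = np.searchsorted(cs, case_scores, side="right")
    per_case = lo + 0.5 * (hi - lo)
    if case_weights is None:
        return float(per_case.sum() / (case_scores.size * n0))
    wsum = case_weights.sum()
    if wsum <= 0:
        raise ValueError("case weights must have positive sum")
    return float((case_weights * per_case).sum() / (wsum * n0))


def empirical_auc(
    data: LabeledScores, case_weights: np.ndarray | None = None
) -> float:
    """(Weighted) empirical AUC of scores for cases versus controls.

    With unit weights this is the standard Mann-Whitney AUC; when all
    scores are identical it evaluates to 0.5.
    """
    cases = data.labels == 1
    if case_weights is not None:
        case_weights = np.asarray(case_weights, dtype=float)
        if case_weights.shape != (int(cases.sum()),):
            raise ValueError("case_weights must align with the cases, in order")
        if (case_weights < 0).any():
            raise ValueError("case weights must be nonnegative")
    return _weighted_auc(data.scores[cases], data.scores[~cases], case_weights)


def _strata_codes(confounders: pd.DataFrame) -> np.ndarray:
    """Integer stratum id per row from the joint confounder levels."""
    if confounders.shape[1] == 0:
        return np.zeros(len(confounders), dtype=np.intp)
    codes = None
    for col in confounders.columns:
        c, _ = pd.factorize(confounders[col].to_numpy(), use_na_sentinel=False)
        codes = c if codes is None else codes * (c.max() + 1) + c
    _, codes = np.unique(codes, return_inverse=True)
    return codes.astype(np.intp)


def _strata_weights(labels: np.ndarray, strata: np.ndarray) -> tuple[np.ndarray, int]:
    """Case weights = (control share of stratum) / (case share of stratum).

    Cases in strata with zero controls get weight 0 (dropped); the count of
    such cases is returned. Weights are normalised to mean 1 over cases.
    """
    cases = labels == 1
    n_strata = int(strata.max()) + 1
    case_counts = np.bincount(strata[cases], minlength=n_strata).astype(float)
    ctrl_counts = np.bincount(strata[~cases], minlength=n_strata).astype(float)
    n_cases, n_ctrl = cases.sum(), (~cases).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (ctrl_counts / n_ctrl) / (case_counts / n_cases)
    ratio = np.where(ctrl_counts == 0, 0.0, ratio)  # cases with no control peers
    w = ratio[strata[cases]]
    dropped = int((w == 0).sum())
    mean = w.mean()
    if mean <= 0:
        raise ValueError("all cases fall in strata without controls")
    return w / mean, dropped


def _model_weights(labels: np.ndarray, confounders: pd.DataFrame) -> np.ndarray:
    """Inverse-odds case weights from a main-effects logistic fit.

    w_i is proportional to P(control | x_i) / P(case | x_i) evaluated at
    each case's confounders, normalised to mean 1 over cases. Non-numeric
    confounder columns are dummy-coded.
    """
    from sklearn.linear_model import LogisticRegression

    if confounders.shape[1] == 0:
        return np.ones(int((labels == 1).sum()))
    X = pd.get_dummies(confounders, drop_first=True, dtype=float).to_numpy()
    clf = LogisticRegression(C=np.inf, max_iter=1000)
    clf.fit(X, labels)
    lin = X @ clf.coef_.ravel() + clf.intercept_[0]
    cases = labels == 1
    w = np.exp(-lin[cases])  # odds of control given x
    return w / w.mean()


def confounder_weights(
    data: LabeledScores, method: str = "strata"
) -> tuple[np.ndarray, int]:
    """Per-case weights that match the case confounder distribution to controls.

    Returns ``(weights, n_dropped_cases)``; weights are ordered as the
    cases appear in ``data`` and have mean 1 (dropped cases carry weight 0
    under the strata engine and are reported, with a warning).
    """
    if method == "strata":
        strata = _strata_codes(data.confounders)
        w, dropped = _strata_weights(data.labels, strata)
        if dropped:
            warnings.warn(
                f"{dropped} case(s) in strata without controls received weight 0",
                stacklevel=2,
            )
        return w, dropped
    if method == "model":
        return _model_weights(data.labels, data.confounders), 0
    raise ValueError(f"unknown weighting method: {method!r}")


def confounder_adjusted_auc(data: LabeledScores, method: str = "strata") -> AUCResult:
    """Point estimate of the confounder-adjusted AUC (no bootstrap)."""
    w, dropped = confounder_weights(data, method)
    auc = empirical_auc(data, w)
    return AUCResult(auc=auc, n_dropped_cases=dropped)


def _resample_indices(rng: np.random.Generator, labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Draw bootstrap indices, redrawing until both classes are present."""
    n = labels.size
    for redraw in range(_MAX_REDRAWS):
        idx = rng.integers(0, n, n)
        s = labels[idx].sum()
        if 0 < s < n:
            return idx, redraw
    raise RuntimeError("bootstrap resampling failed to produce both classes")


def _adjusted_auc_arrays(
    scores: np.ndarray, labels: np.ndarray, strata_or_conf, method: str
) -> float:
    """Fast path used inside the bootstrap loop (no dataclass churn)."""
    cases = labels == 1
    if method == "strata":
        w, _ = _strata_weights(labels, strata_or_conf)
    else:
        w = _model_weights(labels, strata_or_conf)
    return _weighted_auc(scores[cases], scores[~cases], w)


def bootstrap_auc(
    data: LabeledScores,
    method: str = "strata",
    n_boot: int = 1000,
    seed: int | None = None,
) -> AUCResult:
    """Adjusted AUC with bootstrap SE and percentile 95% CI.

    Individuals are resampled with replacement (unstratified); replicates
    that lose a class are redrawn and the redraw count reported. The
    adjustment weights are recomputed inside every replicate. Deterministic
    given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    point = confounder_adjusted_auc(data, method)
    rng = np.random.default_rng(seed)
    strata = _strata_codes(data.confounders) if method == "strata" else None
    reps = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        idx, r = _resample_indices(rng, data.labels)
        redraws += r
        conf = strata[idx] if method == "strata" else data.confounders.iloc[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reps[b] = _adjusted_auc_arrays(data.scores[idx], data.labels[idx], conf, method)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    if redraws:
        logger.info("bootstrap_auc: %d replicate redraws", redraws)
    return AUCResult(
        auc=point.auc,
        se=float(reps.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_redraws=redraws,
        n_dropped_cases=point.n_dropped_cases,
    )


def compare_auc_bootstrap(
    data_a: LabeledScores,
    data_b: LabeledScores,
    method: str = "strata",
    n_boot: int = 1000,
    seed: int | None = None,
) -> AUCComparison:
    """Paired bootstrap z-test of the adjusted-AUC difference (B minus A).

    ``data_a`` and ``data_b`` must describe the same individuals (labels
    and confounders identical) and differ only in scores; each replicate
    applies one shared resample to both models, so the replicate deltas
    capture the correlation between the two AUC estimates.
    """
    if not np.array_equal(data_a.labels, data_b.labels):
        raise ValueError("labels differ between the two models")
    if not data_a.confounders.reset_index(drop=True).equals(
        data_b.confounders.reset_index(drop=True)
    ):
        raise ValueError("confounders differ between the two models")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")

    labels = data_a.labels
    point_a = confounder_adjusted_auc(data_a, method)
    point_b = confounder_adjusted_auc(data_b, method)
    delta = point_b.auc - point_a.auc

    rng = np.random.default_rng(seed)
    strata = _strata_codes(data_a.confounders) if method == "strata" else None
    deltas = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        idx, r = _resample_indices(rng, labels)
        redraws += r
        lab = labels[idx]
        cases = lab == 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if method == "strata":
                w, _ = _strata_weights(lab, strata[idx])
            else:
                w = _model_weights(lab, data_a.confounders.iloc[idx])
        sa = data_a.scores[idx]
        sb = data_b.scores[idx]
        deltas[b] = _weighted_auc(sb[cases], sb[~cases], w) - _weighted_auc(
            sa[cases], sa[~cases], w
        )
    se = float(deltas.std(ddof=1))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    if se > 0:
        z = delta / se
        p = float(2.0 * norm.sf(abs(z)))
    elif delta == 0:
        z, p = 0.0, 1.0
    else:
        warnings.warn("degenerate bootstrap: zero SE with nonzero delta", stacklevel=2)
        z, p = float("inf") if delta > 0 else float("-inf"), 0.0
    if redraws:
        logger.info("compare_auc_bootstrap: %d replicate redraws", redraws)
    return AUCComparison(
        delta=float(delta),
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        z=float(z),
        p_two_sided=p,
        auc_a=point_a,
        auc_b=point_b,
    )
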