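"""Outcome definitions, cohort splitting, and the six nested risk models.

The primary endpoint is advanced neoplasia — colorectal cancer (CRC) or
advanced adenoma (AA) versus everyone else; the secondary endpoint is CRC
only, with AA carriers excluded from the analysis set. Risk models are
maximum-likelihood logistic regressions of the endpoint on standardized
scores plus age and sex, reporting per-SD odds ratios with Wald 95%
intervals. Six models cover every subset of {known-loci CRC score,
genome-wide CRC score} with and without the composite multi-score (MPS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeRecord",
    "EndpointSpec",
    "ADVANCED_NEOPLASIA",
    "CRC_ONLY",
    "PredictorEstimate",
    "ModelFit",
    "MODEL_PREDICTORS",
    "define_outcome",
    "split_cohort",
    "fit_risk_model",
    "run_model_suite",
    "model_suite_table",
]

STATUSES = ("control", "advanced_adenoma", "crc")


@dataclass(frozen=True)
class PhenotypeRecord:
    individual_id: str
    age: float
    sex: str  # "female" | "male"
    platform: str
    status: str  # one of STATUSES

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class EndpointSpec:
    name: str
    case_statuses: frozenset[str]
    control_statuses: frozenset[str]
    excluded_statuses: frozenset[str]


#: CRC or advanced adenoma vs everyone else.
ADVANCED_NEOPLASIA = EndpointSpec(
    "advanced_neoplasia",
    frozenset({"crc", "advanced_adenoma"}),
    frozenset({"control"}),
    frozenset(),
)
#: CRC vs controls; advanced-adenoma carriers are excluded from the analysis.
CRC_ONLY = EndpointSpec(
    "crc_only",
    frozenset({"crc"}),
    frozenset({"control"}),
    frozenset({"advanced_adenoma"}),
)

ENDPOINTS = {e.name: e for e in (ADVANCED_NEOPLASIA, CRC_ONLY)}

#: Predictor sets of the six standard models, keyed by model number.
MODEL_PREDICTORS: dict[int, tuple[str, ...]] = {
    1: ("CRC-KL200",),
    2: ("CRC-LDpred",),
    3: ("CRC-KL200", "CRC-LDpred"),
    4: ("CRC-KL200", "MPS"),
    5: ("CRC-LDpred", "MPS"),
    6: ("CRC-KL200", "CRC-LDpred", "MPS"),
}


@dataclass
class PredictorEstimate:
    name: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class ModelFit:
    model_number: int
    predictors: tuple[str, ...]
    estimates: list[PredictorEstimate]
    covariate_estimates: list[PredictorEstimate]
    intercept: float
    n_cases: int
    n_controls: int
    log_likelihood: float
    sex: str | None = None  # set in sex-stratified fits

    def estimate(self, name: str) -> PredictorEstimate:
        for e in self.estimates:
            if e.name == name:
                return e
        raise KeyError(name)


def define_outcome(
    phenotypes: Sequence[PhenotypeRecord], endpoint: EndpointSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels and inclusion mask for an endpoint definition.

    Returns ``(labels, include)`` where ``include`` is a boolean mask over
    the input order and ``labels`` has one entry per *included* record.
    An empty phenotype list yields empty outputs; otherwise zero cases
    after masking is an error.
    """
    include = np.array(
        [p.status not in endpoint.excluded_statuses for p in phenotypes], dtype=bool
    )
    labels = np.array(
        [int(p.status in endpoint.case_statuses) for p in phenotypes if p.status not in endpoint.excluded_statuses],
        dtype=int,
    )
    if len(phenotypes) and labels.sum() == 0:
        raise ValueError(f"endpoint {endpoint.name}: no cases after masking")
    return labels, include


def split_cohort(
    ids: Sequence[str], fraction: float = 0.5, seed: int | None = None
) -> tuple[list[str], list[str]]:
    """Seeded random split into training and validation id lists.

    The first ``floor(fraction * n)`` of a seeded permutation go to
    training; the split is disjoint and exhaustive.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    ids = list(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(fraction * len(ids)))
    train = [ids[i] for i in perm[:n_train]]
    valid = [ids[i] for i in perm[n_train:]]
    return train, valid


def _wald_rows(names, params, bse, pvalues) -> list[PredictorEstimate]:
    rows = []
    for name, b, se, p in zip(names, params, bse, pvalues):
        rows.append(
            PredictorEstimate(
                name=name,
                coef=float(b),
                se=float(se),
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.96 * se)),
                ci_high=float(np.exp(b + 1.96 * se)),
                p=float(p),
            )
        )
    return rows


def fit_risk_model(
    predictors: pd.DataFrame,
    covariates: pd.DataFrame,
    labels: np.ndarray,
    model_number: int = 0,
    sex: str | None = None,
) -> ModelFit:
    """Maximum-likelihood logistic fit with per-SD odds ratios.

    ``predictors`` should hold standardized scores (so OR is per SD);
    ``covariates`` typically contains centred age and a sex indicator.
    Wald 95% CI = exp(beta +/- 1.96 SE). A rank-deficient design raises,
    naming the collinear columns.
    """
    import statsmodels.api as sm

    y = np.asarray(labels, dtype=float)
    X = pd.concat(
        [predictors.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1
    ).astype(float)
    mat = X.to_numpy()
    if mat.size and np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), mat])) < mat.shape[1] + 1:
        # identify offending columns by incremental rank
        bad, cols = [], [np.ones(len(y))]
        for name in X.columns:
            cand = np.column_stack(cols + [X[name].to_numpy()])
            if np.linalg.matrix_rank(cand) == len(cols):
                bad.append(name)
            else:
                cols.append(X[name].to_numpy())
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    design = sm.add_constant(X, prepend=True)
    res = sm.Logit(y, design).fit(disp=0)
    names = list(design.columns)
    est = _wald_rows(
        names[1:], res.params.iloc[1:], res.bse.iloc[1:], res.pvalues.iloc[1:]
    )
    pred_names = set(predictors.columns)
    return ModelFit(
        model_number=model_number,
        predictors=tuple(predictors.columns),
        estimates=[e for e in est if e.name in pred_names],
        covariate_estimates=[e for e in est if e.name not in pred_names],
        intercept=float(res.params.iloc[0]),
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        log_likelihood=float(res.llf),
        sex=sex,
    )


def run_model_suite(
    scores: pd.DataFrame,
    phenotypes: Sequence[PhenotypeRecord],
    endpoint: EndpointSpec = ADVANCED_NEOPLASIA,
    stratify_sex: bool = False,
) -> list[ModelFit]:
    """Fit the six standard models (or six per sex when stratified).

    ``scores`` must carry columns ``CRC-KL200``, ``CRC-LDpred`` and ``MPS``
    aligned row-wise with ``phenotypes``. Covariates are centred age plus
    a male indicator (dropped within sex strata).
    """
    for col in ("CRC-KL200", "CRC-LDpred", "MPS"):
        if col not in scores.columns:
            raise KeyError(f"scores table lacks required column {col!r}")
    if len(scores) != len(phenotypes):
        raise ValueError("scores and phenotypes are not aligned")

    labels, include = define_outcome(phenotypes, endpoint)
    sub = scores.reset_index(drop=True).loc[include].reset_index(drop=True)
    phen = [p for p, m in zip(phenotypes, include) if m]
    age = np.array([p.age for p in phen], dtype=float)
    male = np.array([1.0 if p.sex == "male" else 0.0 for p in phen])

    def _fit_block(mask: np.ndarray, sex: str | None) -> list[ModelFit]:
        cov = {"age": age[mask] - age[mask].mean()}
        if sex is None:
            cov["male"] = male[mask]
        covdf = pd.DataFrame(cov)
        out = []
        for number, preds in MODEL_PREDICTORS.items():
            out.append(
                fit_risk_model(
                    sub.loc[mask, list(preds)].reset_index(drop=True),
                    covdf,
                    labels[mask],
                    model_number=number,
                    sex=sex,
                )
            )
        return out

    if not stratify_sex:
        return _fit_block(np.ones(len(phen), dtype=bool), None)
    fits: list[ModelFit] = []
    for sex_value in ("female", "male"):
        mask = np.array([p.sex == sex_value for p in phen])
        if mask.any():
            fits.extend(_fit_block(mask, sex_value))
    return fits


def model_suite_table(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Flatten a model suite into a per-predictor OR table."""
    rows = []
    for fit in fits:
        for e in fit.estimates:
            rows.append(
                {
                    "model_no": fit.model_number,
                    "sex": fit.sex or "all",
                    "predictor": e.name,
                    "OR": e.odds_ratio,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p": e.p,
                    "n_cases": fit.n_cases,
                    "n_controls": fit.n_controls,
                }
            )
    return pd.DataFrame(rows)
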