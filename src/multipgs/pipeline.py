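"""End-to-end orchestration of the three-step multi-score workflow.

Step 1 (selection cohort): filter the score catalog, compute and
standardize all surviving scores, tune the penalized selection by
cross-validated confounder-adjusted AUC, and define the composite MPS.

Step 2 (evaluation cohort, training split): compute the two CRC scores
and the MPS, standardize on the training split, and fit the six nested
logistic risk models.

Step 3 (evaluation cohort, validation split): confounder-adjusted AUC of
every model's score-only linear predictor, and the three paired bootstrap
comparisons (model 4 vs 1, 5 vs 2, 6 vs 3).

Standardization moments always come from the split a model was fitted on;
nothing from the validation split flows back into fitting.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import pgs_catalog_io, prs_engine, risk_models
from .cadj_auc import LabeledScores, bootstrap_auc, compare_auc_bootstrap
from .mps_selection import CompositeMPS, PenaltyGrid, build_composite_mps, cv_select
from .pgs_catalog_io import filter_catalog, parse_scoring_file
from .prs_engine import (
    GenotypeMatrix,
    ScoreMatrix,
    apply_standardization,
    compute_score_matrix,
    read_dosage_tsv,
    read_vcf,
    standardize_scores,
)
from .risk_models import (
    ENDPOINTS,
    MODEL_PREDICTORS,
    PhenotypeRecord,
    define_outcome,
    model_suite_table,
    run_model_suite,
    split_cohort,
)
from .synthetic_data import read_phenotype_tsv

__all__ = ["PipelineConfig", "PipelineError", "run_step1", "run_step2_step3", "run_pipeline"]

logger = logging.getLogger(__name__)

#: validation comparisons: composite-augmented model vs its base model
COMPARISON_PAIRS = ((4, 1), (5, 2), (6, 3))


class PipelineError(RuntimeError):
    """Raised with the failing stage name prefixed to the message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and settings for a full three-step run.

    ``selection_*`` paths feed step 1; ``evaluation_*`` paths feed steps
    2-3. When the evaluation paths are omitted the selection cohort is
    reused (with a warning: selection and evaluation should be
    independent cohorts).
    """

    scores_dir: str = ""
    selection_genotypes: str = ""
    selection_phenotypes: str = ""
    evaluation_genotypes: str = ""
    evaluation_phenotypes: str = ""
    out_dir: str = "."
    # step 1
    max_missing: float = 0.20
    folds: int = 10
    alphas: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_lambdas: int = 50
    selection_seed: int = 11
    selection_confounders: tuple[str, ...] = ("age_decade", "sex", "platform")
    # step 2
    endpoint: str = "advanced_neoplasia"
    split_fraction: float = 0.5
    split_seed: int = 23
    stratify_sex: bool = False
    # step 3
    n_boot: int = 1000
    boot_seed: int = 17
    auc_confounders: tuple[str, ...] = ("age_decade", "sex")
    auc_method: str = "strata"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("alphas", "selection_confounders", "auc_confounders"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def digest(self) -> str:
        """Hash of the analysis settings (output location excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _read_genotypes(path: str, stage: str) -> GenotypeMatrix:
    if not os.path.exists(path):
        raise PipelineError(stage, f"genotype file not found: {path}")
    if path.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_dosage_tsv(path)


def _confounder_frame(
    phenotypes: list[PhenotypeRecord], names: tuple[str, ...]
) -> pd.DataFrame:
    cols = {}
    for name in names:
        if name == "age":
            cols[name] = [p.age for p in phenotypes]
        elif name == "age_decade":
            cols[name] = [10 * int(p.age // 10) for p in phenotypes]
        elif name == "sex":
            cols[name] = [p.sex for p in phenotypes]
        elif name == "platform":
            cols[name] = [p.platform for p in phenotypes]
        else:
            raise PipelineError("config", f"unknown confounder {name!r}")
    return pd.DataFrame(cols)


def _covariate_frame(phenotypes: list[PhenotypeRecord], with_platform: bool) -> pd.DataFrame:
    age = np.array([p.age for p in phenotypes], dtype=float)
    male = np.array([1.0 if p.sex == "male" else 0.0 for p in phenotypes])
    df = pd.DataFrame({"age": age - age.mean(), "male": male})
    if with_platform:
        plat = pd.get_dummies(
            pd.Series([p.platform for p in phenotypes]), prefix="platform",
            drop_first=True, dtype=float,
        )
        df = pd.concat([df, plat], axis=1)
    return df


def run_step1(config: PipelineConfig) -> dict:
    """Catalog filter -> scoring -> standardization -> CV selection -> composite.

    Returns the model document (also written to ``out_dir/mps_model.yaml``):
    selected alpha/lambda, nonzero components, CV table, seeds, and the
    selection-cohort standardization moments.
    """
    t0 = time.time()
    if not os.path.isdir(config.scores_dir):
        raise PipelineError("step1/catalog", f"scores dir not found: {config.scores_dir}")
    paths = sorted(
        glob.glob(os.path.join(config.scores_dir, "*.txt"))
        + glob.glob(os.path.join(config.scores_dir, "*.txt.gz"))
    )
    if not paths:
        raise PipelineError("step1/catalog", f"no scoring files in {config.scores_dir}")
    catalog = [parse_scoring_file(p) for p in paths]
    # the CRC scores are inputs to step 2, never candidates for selection
    candidates = [s for s in catalog if s.pgs_id not in ("CRC-KL200", "CRC-LDpred")]

    genotypes = _read_genotypes(config.selection_genotypes, "step1/genotypes")
    phenotypes = read_phenotype_tsv(config.selection_phenotypes)
    if [p.individual_id for p in phenotypes] != list(genotypes.individual_ids):
        raise PipelineError("step1/phenotypes", "phenotype ids do not match genotype ids")

    report = filter_catalog(candidates, genotypes.variant_index(), config.max_missing)
    kept = [s for s in candidates if s.pgs_id in set(report.kept)]
    logger.info("step1: %d/%d catalog entries kept", len(kept), len(candidates))
    if not kept:
        raise PipelineError("step1/filter", "no scoring files survive the catalog filter")
    os.makedirs(config.out_dir, exist_ok=True)
    pgs_catalog_io.write_filter_report(
        report, candidates, os.path.join(config.out_dir, "catalog_filter.tsv")
    )

    raw = compute_score_matrix(kept, genotypes)
    scores = standardize_scores(raw)
    # selection always uses the broad endpoint: CRC or advanced adenoma
    labels, include = define_outcome(phenotypes, ENDPOINTS["advanced_neoplasia"])
    if not include.all():  # crc_only drops AA carriers; subset everything
        keep_idx = np.flatnonzero(include)
        scores = ScoreMatrix(
            [scores.individual_ids[i] for i in keep_idx],
            list(scores.score_ids),
            scores.values[keep_idx],
            standardized=True, means=scores.means, sds=scores.sds,
        )
        phenotypes = [phenotypes[i] for i in keep_idx]

    covariates = _covariate_frame(phenotypes, with_platform=True)
    confounders = _confounder_frame(phenotypes, config.selection_confounders)
    grid = PenaltyGrid(
        alphas=config.alphas, n_folds=config.folds, n_lambdas=config.n_lambdas
    )
    fit = cv_select(
        scores, covariates, labels, confounders, grid,
        seed=config.selection_seed, auc_method=config.auc_method,
    )
    _, composite = build_composite_mps(fit, scores)

    doc = {
        "config_digest": config.digest(),
        "selection_seed": config.selection_seed,
        "alpha": float(fit.alpha),
        "lambda": float(fit.lam),
        "intercept": float(fit.intercept),
        "covariate_coefficients": {k: float(v) for k, v in fit.covariate_coefficients.items()},
        "components": {k: float(v) for k, v in composite.components.items()},
        "composite_mean": composite.mean,
        "composite_sd": composite.sd,
        "standardization": {
            pid: {"mean": float(m), "sd": float(s)}
            for pid, m, s in zip(scores.score_ids, scores.means, scores.sds)
        },
        "cv_table": [
            {k: float(v) for k, v in row.items()}
            for row in fit.cv_table.to_dict(orient="records")
        ],
        "n_kept_catalog": len(kept),
    }
    logger.info("step1 finished in %.1fs", time.time() - t0)
    with open(os.path.join(config.out_dir, "mps_model.yaml"), "wt") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return doc


def _score_only_predictor(fit: risk_models.ModelFit, scores: pd.DataFrame) -> np.ndarray:
    """Linear predictor restricted to the score terms of a fitted model."""
    lp = np.zeros(len(scores))
    for e in fit.estimates:
        lp += e.coef * scores[e.name].to_numpy()
    return lp


def run_step2_step3(config: PipelineConfig, mps_model: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train/validate the six risk models and compare adjusted AUCs.

    Writes ``models.tsv`` (per-predictor ORs from the training split) and
    ``auc_report.tsv`` (validation AUC per model plus the three paired
    comparisons) under ``config.out_dir``; returns both tables.
    """
    geno_path = config.evaluation_genotypes or config.selection_genotypes
    phen_path = config.evaluation_phenotypes or config.selection_phenotypes
    if not config.evaluation_genotypes:
        logger.warning("no evaluation cohort given; reusing the selection cohort")
    genotypes = _read_genotypes(geno_path, "step2/genotypes")
    phenotypes = read_phenotype_tsv(phen_path)

    needed = set(mps_model["components"]) | {"CRC-KL200", "CRC-LDpred"}
    paths = sorted(
        glob.glob(os.path.join(config.scores_dir, "*.txt"))
        + glob.glob(os.path.join(config.scores_dir, "*.txt.gz"))
    )
    catalog = {s.pgs_id: s for p in paths for s in [parse_scoring_file(p)]}
    missing = needed - set(catalog)
    if missing:
        raise PipelineError("step2/scores", f"scoring files missing for: {sorted(missing)}")

    raw = compute_score_matrix([catalog[p] for p in sorted(needed)], genotypes)

    endpoint = ENDPOINTS[config.endpoint]
    labels_all, include = define_outcome(phenotypes, endpoint)
    idx_all = np.flatnonzero(include)
    phen = [phenotypes[i] for i in idx_all]
    ids = [p.individual_id for p in phen]

    train_ids, valid_ids = split_cohort(ids, config.split_fraction, config.split_seed)
    pos = {pid: i for i, pid in enumerate(raw.individual_ids)}
    phen_pos = {p.individual_id: k for k, p in enumerate(phen)}

    def _subset(id_list: list[str]) -> tuple[ScoreMatrix, list[PhenotypeRecord], np.ndarray]:
        rows = [pos[i] for i in id_list]
        sm = ScoreMatrix(id_list, list(raw.score_ids), raw.values[rows])
        ph = [phen[phen_pos[i]] for i in id_list]
        lab = labels_all[[phen_pos[i] for i in id_list]]
        return sm, ph, lab

    raw_train, phen_train, y_train = _subset(train_ids)
    raw_valid, phen_valid, y_valid = _subset(valid_ids)

    # training-split moments applied to both splits (leakage guard)
    std_train = standardize_scores(raw_train)
    std_valid = apply_standardization(raw_valid, std_train)

    composite = CompositeMPS(
        components=mps_model["components"], mean=0.0, sd=1.0
    )
    mps_train_raw = composite.apply(std_train)
    mps_mean, mps_sd = float(mps_train_raw.mean()), float(mps_train_raw.std(ddof=1))
    composite = CompositeMPS(mps_model["components"], mean=mps_mean, sd=mps_sd)
    # re-apply with the training moments folded in
    def _three_scores(std: ScoreMatrix) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "CRC-KL200": std.column("CRC-KL200"),
                "CRC-LDpred": std.column("CRC-LDpred"),
                "MPS": composite.apply(std),
            }
        )

    scores_train = _three_scores(std_train)
    scores_valid = _three_scores(std_valid)

    fits = run_model_suite(scores_train, phen_train, endpoint, stratify_sex=config.stratify_sex)
    models_tsv = model_suite_table(fits)
    os.makedirs(config.out_dir, exist_ok=True)
    models_tsv.to_csv(os.path.join(config.out_dir, "models.tsv"), sep="\t", index=False)

    confounders_valid = _confounder_frame(phen_valid, config.auc_confounders)
    main_fits = {f.model_number: f for f in fits if f.sex is None}

    auc_rows = []
    lp = {}
    for number, fit in sorted(main_fits.items()):
        lp[number] = _score_only_predictor(fit, scores_valid)
        data = LabeledScores(lp[number], y_valid, confounders_valid)
        res = bootstrap_auc(
            data, config.auc_method, config.n_boot, seed=config.boot_seed + number
        )
        auc_rows.append(
            {
                "row": f"model_{number}",
                "predictors": "+".join(MODEL_PREDICTORS[number]),
                "auc": res.auc, "se": res.se,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "z": float("nan"), "p": float("nan"),
                "n_boot": res.n_boot, "seed": config.boot_seed + number,
            }
        )
    for aug, base in COMPARISON_PAIRS:
        cmp = compare_auc_bootstrap(
            LabeledScores(lp[base], y_valid, confounders_valid),
            LabeledScores(lp[aug], y_valid, confounders_valid),
            config.auc_method, config.n_boot, seed=config.boot_seed + 100 + aug,
        )
        auc_rows.append(
            {
                "row": f"model_{aug}_minus_model_{base}",
                "predictors": "delta",
                "auc": cmp.delta, "se": cmp.se,
                "ci_low": cmp.ci_low, "ci_high": cmp.ci_high,
                "z": cmp.z, "p": cmp.p_two_sided,
                "n_boot": config.n_boot, "seed": config.boot_seed + 100 + aug,
            }
        )
    auc_report = pd.DataFrame(auc_rows)
    auc_report.insert(0, "config_digest", config.digest())
    auc_report.to_csv(os.path.join(config.out_dir, "auc_report.tsv"), sep="\t", index=False)
    return models_tsv, auc_report


def run_pipeline(config: PipelineConfig) -> dict:
    """All three steps; returns {'mps_model', 'models', 'auc_report'}."""
    mps_model = run_step1(config)
    models_tsv, auc_report = run_step2_step3(config, mps_model)
    return {"mps_model": mps_model, "models": models_tsv, "auc_report": auc_report}
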