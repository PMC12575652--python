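"""Polygenic score computation from genotype dosages.

A polygenic score for an individual is the weighted sum of effect-allele
dosages over the variants of one scoring file. Genotypes store the dosage
of a designated alt allele; when a scoring file's effect allele is the
panel's ref allele the dosage is reflected (``2 - d``) before weighting.
Scores are standardized column-wise to mean 0, SD 1, with the moments
recorded so the same affine transform can be applied to held-out samples.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd

from .pgs_catalog_io import ScoringFile, variant_key

__all__ = [
    "GenotypeMatrix",
    "ScoreMatrix",
    "MatchedVariant",
    "match_variants",
    "compute_raw_prs",
    "compute_score_matrix",
    "standardize_scores",
    "apply_standardization",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
]

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    ``dosages[i, j]`` counts copies of ``alt[j]`` carried by individual i,
    in [0, 2] (fractional for imputed data); missing entries are NaN.
    """

    individual_ids: list[str]
    chrom: np.ndarray  # object/str array, length m
    position: np.ndarray  # int array, length m
    ref: np.ndarray  # str array, length m
    alt: np.ndarray  # str array, length m
    dosages: np.ndarray  # float (n, m), NaN = missing

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if not (len(self.chrom) == len(self.position) == len(self.ref) == len(self.alt) == m):
            raise ValueError("variant metadata length does not match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual_ids")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError(f"{int(bad)} dosage entries outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_keys(self) -> list[str]:
        return [
            variant_key(c, p, r, a)
            for c, p, r, a in zip(self.chrom, self.position, self.ref, self.alt)
        ]

    def variant_index(self) -> set[str]:
        """Set of orientation-free variant keys, for catalog overlap checks."""
        return set(self.variant_keys())


@dataclass
class ScoreMatrix:
    """Individuals x scores value table, raw or standardized."""

    individual_ids: list[str]
    score_ids: list[str]
    values: np.ndarray  # (n, K)
    standardized: bool = False
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.individual_ids), len(self.score_ids)):
            raise ValueError("values shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score values must be finite")

    def column(self, score_id: str) -> np.ndarray:
        return self.values[:, self.score_ids.index(score_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.score_ids
        )


class MatchedVariant(NamedTuple):
    column: int
    orientation: Literal["as_is", "swapped"]
    effect_weight: float


def match_variants(
    scoring: ScoringFile,
    genotypes: GenotypeMatrix,
    drop_ambiguous: bool = False,
) -> list[MatchedVariant]:
    """Match a scoring file's variants to genotype columns by position and alleles.

    ``as_is``: the effect allele is the panel's alt allele (dosage used
    directly). ``swapped``: the effect allele is the ref allele (dosage
    reflected). A position present in both but with a different allele
    pair is unmatched and logged. Strand-ambiguous pairs (A/T, C/G) are
    matched as-is unless ``drop_ambiguous``.
    """
    by_pos: dict[tuple[str, int], list[int]] = {}
    for j in range(genotypes.n_variants):
        by_pos.setdefault((str(genotypes.chrom[j]), int(genotypes.position[j])), []).append(j)

    matched: list[MatchedVariant] = []
    n_unmatched = 0
    for v in scoring.variants:
        parts = v.variant_id.split(":")
        if len(parts) < 2:
            n_unmatched += 1  # rsID-only record, no positional lookup
            continue
        pos_key = (parts[0], int(parts[1]))
        hit = None
        for j in by_pos.get(pos_key, ()):
            ref, alt = genotypes.ref[j], genotypes.alt[j]
            if v.effect_allele == alt and v.other_allele == ref:
                hit = MatchedVariant(j, "as_is", v.effect_weight)
            elif v.effect_allele == ref and v.other_allele == alt:
                hit = MatchedVariant(j, "swapped", v.effect_weight)
            else:
                continue
            if drop_ambiguous and frozenset({ref, alt}) in AMBIGUOUS_PAIRS:
                hit = None
            break
        if hit is None:
            n_unmatched += 1
            logger.debug("unmatched variant %s (%s/%s)", v.variant_id, v.effect_allele, v.other_allele)
        else:
            matched.append(hit)
    if n_unmatched:
        logger.info("%s: %d/%d variants unmatched", scoring.pgs_id, n_unmatched, len(scoring))
    return matched


def compute_raw_prs(
    scoring: ScoringFile,
    genotypes: GenotypeMatrix,
    drop_ambiguous: bool = False,
) -> np.ndarray:
    """Weighted sum of effect-allele dosages: score_i = sum_j w_j * d_ij.

    Missing dosages at a matched variant are imputed with that variant's
    sample-mean dosage (the standard scoring convention; preserves the
    score mean). Raises if no variant matches.
    """
    matched = match_variants(scoring, genotypes, drop_ambiguous=drop_ambiguous)
    if not matched:
        raise ValueError(
            f"{scoring.pgs_id}: no variants match the genotype panel; "
            "run the catalog filter before scoring"
        )
    cols = np.array([m.column for m in matched])
    weights = np.array([m.effect_weight for m in matched])
    swapped = np.array([m.orientation == "swapped" for m in matched])

    d = genotypes.dosages[:, cols].astype(float, copy=True)
    if np.isnan(d).any():
        col_means = np.nanmean(d, axis=0)
        # a fully missing column has no sample mean; treat as dosage 0
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        nan_mask = np.isnan(d)
        d[nan_mask] = np.broadcast_to(col_means, d.shape)[nan_mask]
    # effect dosage is 2 - d when the effect allele is the ref allele
    signed = np.where(swapped, -weights, weights)
    offset = float(np.sum(2.0 * weights[swapped]))
    return d @ signed + offset


def compute_score_matrix(
    catalog: Iterable[ScoringFile],
    genotypes: GenotypeMatrix,
    drop_ambiguous: bool = False,
) -> ScoreMatrix:
    """Raw scores for every scoring file in a catalog, one column each."""
    ids: list[str] = []
    columns: list[np.ndarray] = []
    for scoring in catalog:
        ids.append(scoring.pgs_id)
        columns.append(compute_raw_prs(scoring, genotypes, drop_ambiguous=drop_ambiguous))
    values = np.column_stack(columns) if columns else np.empty((genotypes.n_individuals, 0))
    return ScoreMatrix(list(genotypes.individual_ids), ids, values)


def standardize_scores(scores: ScoreMatrix) -> ScoreMatrix:
    """Column-wise (x - mean) / sd using the full-sample mean and sample SD.

    SD uses the n-1 denominator; the moments are recorded on the result so
    the identical transform can be applied to new samples
    (:func:`apply_standardization`). Zero-variance columns are an error.
    """
    means = scores.values.mean(axis=0)
    sds = scores.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [scores.score_ids[j] for j in zero]
        raise ValueError(f"zero-variance score column(s): {names}")
    values = (scores.values - means) / sds
    return ScoreMatrix(
        list(scores.individual_ids),
        list(scores.score_ids),
        values,
        standardized=True,
        means=means,
        sds=sds,
    )


def apply_standardization(scores: ScoreMatrix, reference: ScoreMatrix) -> ScoreMatrix:
    """Apply a reference sample's recorded moments to new raw scores.

    Used to carry training-split standardization onto a validation split
    without leaking validation moments into the model.
    """
    if reference.means is None or reference.sds is None:
        raise ValueError("reference ScoreMatrix carries no recorded moments")
    if list(scores.score_ids) != list(reference.score_ids):
        raise ValueError("score_ids differ between sample and reference")
    values = (scores.values - reference.means) / reference.sds
    return ScoreMatrix(
        list(scores.individual_ids),
        list(scores.score_ids),
        values,
        standardized=True,
        means=reference.means,
        sds=reference.sds,
    )


# ---------------------------------------------------------------------------
# Genotype readers / writers


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Dosage TSV: rows individuals, columns chrom:pos:ref:alt, NaN = missing."""
    cols = [
        f"{c}:{p}:{r}:{a}"
        for c, p, r, a in zip(genotypes.chrom, genotypes.position, genotypes.ref, genotypes.alt)
    ]
    df = pd.DataFrame(genotypes.dosages, index=genotypes.individual_ids, columns=cols)
    df.to_csv(path, sep="\t", index_label="individual_id")


def read_dosage_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    """Read the dosage TSV dialect written by :func:`write_dosage_tsv`.

    Column headers are ``chrom:pos:ref:alt``; the stored orientation (which
    allele the dosage counts) is taken from the header order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    chrom, position, ref, alt = [], [], [], []
    for col in df.columns:
        c, p, r, a = col.split(":")
        chrom.append(c)
        position.append(int(p))
        ref.append(r)
        alt.append(a)
    return GenotypeMatrix(
        individual_ids=[str(i) for i in df.index],
        chrom=np.array(chrom, dtype=object),
        position=np.array(position, dtype=int),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosages=df.to_numpy(dtype=float),
    )


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read biallelic variants from a VCF into a dosage matrix.

    The DS FORMAT field is used when present; otherwise GT is converted to
    0/1/2 (missing genotypes become NaN). Multi-allelic records are skipped.
    """
    from cyvcf2 import VCF  # deferred: optional heavy dependency

    vcf = VCF(os.fspath(path), gts012=True)
    individual_ids = list(vcf.samples)
    chrom, position, ref, alt, rows = [], [], [], [], []
    for record in vcf:
        if len(record.ALT) != 1:
            logger.debug("skipping multi-allelic record at %s:%d", record.CHROM, record.POS)
            continue
        try:
            ds = record.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where((dos < 0) | (dos > 2), np.nan, dos)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=hom-alt (with gts012), 3=unknown
            gt = np.asarray(record.gt_types, dtype=float)
            dos = np.where(gt == 3, np.nan, gt)
        chrom.append(record.CHROM)
        position.append(record.POS)
        ref.append(record.REF)
        alt.append(record.ALT[0])
        rows.append(dos)
    dosages = (
        np.column_stack(rows) if rows else np.empty((len(individual_ids), 0))
    )
    return GenotypeMatrix(
        individual_ids=individual_ids,
        chrom=np.array(chrom, dtype=object),
        position=np.array(position, dtype=int),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosages=dosages,
    )
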