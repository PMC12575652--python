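"""Synthetic cohorts, trait weight vectors, and catalog fixtures.

The generators emulate the statistical structure the analysis assumes,
at desk scale and with exact bookkeeping:

* genotypes are independent biallelic variants in Hardy-Weinberg
  equilibrium (no linkage disequilibrium) with uniform allele frequencies;
* disease risk follows a liability-threshold model: a genetic value built
  from a sparse causal weight vector, plus age and sex effects, plus
  Gaussian noise; the top liability quantile becomes CRC, the band below
  it advanced adenoma, the rest controls;
* secondary traits share a configurable fraction of their causal variants
  with the CRC liability (pleiotropy), which is what gives their scores
  predictive value for CRC;
* "published" score weights are the true causal weights plus Gaussian
  noise, written as PGS-Catalog-dialect scoring files with controllable
  variant missingness.

Everything is bit-reproducible from (config, seed); independent RNG
streams per stage keep the stages individually reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pgs_catalog_io import (
    CatalogFilterReport,
    ScoringFile,
    VariantRecord,
    variant_key,
)
from .prs_engine import GenotypeMatrix
from .risk_models import PhenotypeRecord

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_trait_weights",
    "simulate_phenotypes",
    "simulate_cohort",
    "emit_scoring_files",
    "make_catalog_fixture",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "write_vcf",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for the liability-threshold case-control simulator.

    Defaults describe the standard scenario: 10,000 individuals, 1,000
    variants, 10 secondary traits of which three share half their causal
    variants with the CRC liability, SNP heritability 0.3 on the
    liability scale (within reported common-variant estimates for CRC),
    5% CRC prevalence atop a 10% advanced-adenoma band, modest age and
    sex effects, and published weights perturbed by noise with SD twice
    the causal-weight SD — calibrated so the noisy published CRC score
    reaches a confounder-adjusted AUC near 0.60, the operating point
    reported for known-loci CRC scores.
    """

    n_individuals: int = 10_000
    m_variants: int = 1_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 10
    shared_causal_fraction: tuple[float, ...] = (0.5, 0.5, 0.5, 0, 0, 0, 0, 0, 0, 0)
    n_causal: int = 100
    h2_liability: float = 0.3
    crc_threshold_quantile: float = 0.95
    aa_band_quantile: float = 0.85
    age_effect: float = 0.3
    sex_effect: float = 0.2
    weight_noise_sd: float = 2.0  # relative to the SD of the causal weights
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if len(self.shared_causal_fraction) != self.n_traits:
            raise ValueError("shared_causal_fraction needs one entry per trait")
        if any(not 0 <= f <= 1 for f in self.shared_causal_fraction):
            raise ValueError("shared_causal_fraction entries must lie in [0, 1]")
        if not 0 <= self.h2_liability <= 1:
            raise ValueError("h2_liability must lie in [0, 1]")
        if not self.aa_band_quantile < self.crc_threshold_quantile:
            raise ValueError("aa_band_quantile must be below crc_threshold_quantile")
        if self.n_causal > self.m_variants:
            raise ValueError("n_causal cannot exceed m_variants")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be nonnegative")


@dataclass
class TruthRecord:
    """Ground truth kept alongside simulated outputs for recovery tests."""

    mafs: np.ndarray
    crc_weights: np.ndarray  # (m,) true causal weights of the CRC liability
    trait_weights: np.ndarray  # (K, m) true causal weights per secondary trait
    published_trait_weights: np.ndarray  # (K, m) noisy, as written to files
    published_crc_weights: np.ndarray  # (m,) noisy CRC weights
    crc_causal: np.ndarray  # causal variant indices of the CRC liability
    trait_causal: list[np.ndarray]
    liability: np.ndarray | None = None  # per-individual, set by simulate_phenotypes
    genetic_value: np.ndarray | None = None
    seed: int = 0


def _stream(config: SimulationConfig, stage: int, replicate: int = 0) -> np.random.Generator:
    # independent, reproducible substreams; stage 0 reserved for MAFs
    return np.random.default_rng([config.seed, stage, replicate])


def _draw_mafs(config: SimulationConfig) -> np.ndarray:
    rng = _stream(config, 0)
    return rng.uniform(*config.maf_range, size=config.m_variants)


_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]


def _variant_metadata(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    m = config.m_variants
    chrom = np.array(["1"] * m, dtype=object)
    position = np.arange(1, m + 1) * 100
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    ref = np.array([p[0] for p in pairs], dtype=object)
    alt = np.array([p[1] for p in pairs], dtype=object)
    return chrom, position, ref, alt


def simulate_genotypes(config: SimulationConfig, replicate: int = 0) -> GenotypeMatrix:
    """HWE genotypes: dosage_ij ~ Binomial(2, MAF_j), variants independent.

    ``replicate`` draws an independent cohort from the *same* variant
    universe (identical MAFs and metadata) — e.g. a selection cohort
    (replicate 0) and an evaluation cohort (replicate 1) sharing truth.
    """
    mafs = _draw_mafs(config)
    rng = _stream(config, 1, replicate)
    dosages = rng.binomial(2, mafs, size=(config.n_individuals, config.m_variants))
    chrom, position, ref, alt = _variant_metadata(config)
    return GenotypeMatrix(
        individual_ids=[f"c{replicate}_ind_{i:06d}" for i in range(config.n_individuals)],
        chrom=chrom,
        position=position,
        ref=ref,
        alt=alt,
        dosages=dosages.astype(float),
    )


def simulate_trait_weights(config: SimulationConfig) -> tuple[np.ndarray, TruthRecord]:
    """Causal weights for the CRC liability and K pleiotropic traits.

    The CRC liability has ``n_causal`` causal variants with Gaussian
    effects scaled so the centred genetic value has variance
    ``h2_liability`` (variance of dosage j is 2 maf_j (1 - maf_j)). Trait
    k reuses the CRC weights on a ``shared_causal_fraction[k]`` share of
    its causal set and draws fresh effects, on the same scale, for the
    remainder (picked from non-CRC-causal variants). Published versions
    add N(0, (weight_noise_sd * SD(causal weights))^2) noise on the causal
    entries. Returns the (K+1, m) stacked true weights (CRC last) and the
    full TruthRecord.
    """
    mafs = _draw_mafs(config)
    rng = _stream(config, 2)
    m, nc = config.m_variants, config.n_causal

    crc_causal = rng.choice(m, size=nc, replace=False)
    raw = rng.normal(size=nc)
    var_dos = 2 * mafs * (1 - mafs)
    scale = np.sqrt(config.h2_liability / np.sum(raw**2 * var_dos[crc_causal]))
    crc_w = np.zeros(m)
    crc_w[crc_causal] = raw * scale
    wsd = float(np.std(crc_w[crc_causal], ddof=1)) if nc > 1 else abs(float(crc_w[crc_causal]))

    non_crc = np.setdiff1d(np.arange(m), crc_causal)
    trait_w = np.zeros((config.n_traits, m))
    trait_causal: list[np.ndarray] = []
    for k, frac in enumerate(config.shared_causal_fraction):
        n_shared = int(round(frac * nc))
        shared = rng.choice(crc_causal, size=n_shared, replace=False)
        private = rng.choice(non_crc, size=nc - n_shared, replace=False)
        causal = np.concatenate([shared, private])
        trait_causal.append(np.sort(causal))
        trait_w[k, shared] = crc_w[shared]
        fresh = rng.normal(size=nc - n_shared)
        if nc - n_shared:
            fresh_scale = np.sqrt(
                config.h2_liability / np.sum(fresh**2 * var_dos[private])
            )
            trait_w[k, private] = fresh * fresh_scale

    noise_sd = config.weight_noise_sd * wsd
    pub_trait = trait_w.copy()
    pub_crc = crc_w.copy()
    if noise_sd > 0:
        for k in range(config.n_traits):
            idx = trait_causal[k]
            pub_trait[k, idx] += rng.normal(0, noise_sd, size=idx.size)
        pub_crc[crc_causal] += rng.normal(0, noise_sd, size=nc)

    truth = TruthRecord(
        mafs=mafs,
        crc_weights=crc_w,
        trait_weights=trait_w,
        published_trait_weights=pub_trait,
        published_crc_weights=pub_crc,
        crc_causal=np.sort(crc_causal),
        trait_causal=trait_causal,
        seed=config.seed,
    )
    stacked = np.vstack([trait_w, crc_w[None, :]])
    return stacked, truth


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: TruthRecord,
    config: SimulationConfig,
    replicate: int = 0,
) -> list[PhenotypeRecord]:
    """Liability-threshold phenotypes with age/sex effects.

    liability = G + age_effect * z(age) + sex_effect * male + N(0, 1-h2),
    with G the centred genetic value. Status is assigned by empirical
    liability quantiles: above ``crc_threshold_quantile`` -> crc, between
    ``aa_band_quantile`` and it -> advanced_adenoma, else control. Ages
    are N(65, 10^2) truncated to [40, 90]; sex is balanced; platform has
    three uniform categories.
    """
    rng = _stream(config, 3, replicate)
    n = genotypes.n_individuals
    centred = genotypes.dosages - 2 * truth.mafs
    g = centred @ truth.crc_weights

    age = rng.normal(65, 10, size=n)
    age = np.clip(age, 40, 90)
    z_age = (age - age.mean()) / age.std(ddof=1)
    male = rng.integers(0, 2, size=n)
    platform = rng.integers(0, 3, size=n)
    env = rng.normal(0, np.sqrt(max(1 - config.h2_liability, 0)), size=n)

    liability = g + config.age_effect * z_age + config.sex_effect * male + env
    crc_cut = np.quantile(liability, config.crc_threshold_quantile)
    aa_cut = np.quantile(liability, config.aa_band_quantile)
    status = np.where(
        liability > crc_cut, "crc", np.where(liability > aa_cut, "advanced_adenoma", "control")
    )
    truth.liability = liability
    truth.genetic_value = g

    return [
        PhenotypeRecord(
            individual_id=genotypes.individual_ids[i],
            age=float(age[i]),
            sex="male" if male[i] else "female",
            platform=f"platform_{platform[i]}",
            status=str(status[i]),
        )
        for i in range(n)
    ]


def simulate_cohort(
    config: SimulationConfig, replicate: int = 0
) -> tuple[GenotypeMatrix, TruthRecord, list[PhenotypeRecord]]:
    """Genotypes, truth and phenotypes for one cohort in a single call.

    Different ``replicate`` values give independent cohorts that share the
    same variant universe and causal weights (the TruthRecord is identical
    up to the per-cohort liability arrays).
    """
    genotypes = simulate_genotypes(config, replicate)
    _, truth = simulate_trait_weights(config)
    phenotypes = simulate_phenotypes(genotypes, truth, config, replicate)
    return genotypes, truth, phenotypes


# ---------------------------------------------------------------------------
# Scoring-file emission


def _scoring_rows(
    weights: np.ndarray,
    causal: np.ndarray,
    genotypes: GenotypeMatrix,
    missingness: float,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Variant rows for one published score; a fraction of rows is moved to
    positions absent from the genotype panel to inject missingness."""
    n_missing = int(round(missingness * causal.size))
    missing_set = set(rng.choice(causal, size=n_missing, replace=False).tolist())
    max_pos = int(genotypes.position.max())
    rows = []
    for j in causal:
        if j in missing_set:
            pos = max_pos + 100 * (int(j) + 1)  # guaranteed off-panel
        else:
            pos = int(genotypes.position[j])
        rows.append(
            VariantRecord(
                variant_id=f"{genotypes.chrom[j]}:{pos}",
                effect_allele=str(genotypes.alt[j]),
                other_allele=str(genotypes.ref[j]),
                effect_weight=float(weights[j]),
            )
        )
    return rows


def _write_scoring_file(path: str, scoring: ScoringFile) -> None:
    with open(path, "wt") as fh:
        fh.write(f"#pgs_id={scoring.pgs_id}\n")
        fh.write(f"#trait_reported={scoring.trait_label}\n")
        fh.write("rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n")
        for i, v in enumerate(scoring.variants):
            chrom, pos = v.variant_id.split(":")
            fh.write(
                f"rs{chrom}_{pos}\t{chrom}\t{pos}\t{v.effect_allele}\t{v.other_allele}\t{v.effect_weight!r}\n"
            )


def emit_scoring_files(
    truth: TruthRecord,
    genotypes: GenotypeMatrix,
    out_dir: str | os.PathLike,
    missingness: float | list[float] = 0.0,
    trait_labels: list[str] | None = None,
    include_crc_files: bool = True,
    seed: int = 0,
) -> list[str]:
    """Write one PGS-Catalog-dialect file per secondary trait.

    ``missingness`` (scalar or per-trait) is the fraction of each file's
    variants relocated to off-panel positions. With ``include_crc_files``
    two extra files are written: ``CRC-KL200`` from the noisy published
    CRC weights and ``CRC-LDpred`` from the noiseless true weights
    (emulating a known-loci score and a stronger genome-wide score).
    Weights round-trip exactly through ``parse_scoring_file`` (written
    with ``repr``). Returns the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    K = truth.trait_weights.shape[0]
    if isinstance(missingness, (int, float)):
        missingness = [float(missingness)] * K
    if len(missingness) != K:
        raise ValueError("need one missingness fraction per trait")
    if any(not 0 <= f < 1 for f in missingness):
        raise ValueError("missingness fractions must lie in [0, 1)")
    if trait_labels is None:
        trait_labels = [f"synthetic trait {k:02d}" for k in range(K)]
    rng = np.random.default_rng([seed, 17])

    paths = []
    for k in range(K):
        scoring = ScoringFile(
            pgs_id=f"PGS_SYN{k:04d}",
            trait_label=trait_labels[k],
            variants=_scoring_rows(
                truth.published_trait_weights[k], truth.trait_causal[k],
                genotypes, missingness[k], rng,
            ),
        )
        path = os.path.join(out_dir, f"{scoring.pgs_id}.txt")
        _write_scoring_file(path, scoring)
        paths.append(path)
    if include_crc_files:
        for pgs_id, weights in (
            ("CRC-KL200", truth.published_crc_weights),
            ("CRC-LDpred", truth.crc_weights),
        ):
            scoring = ScoringFile(
                pgs_id=pgs_id,
                trait_label="colorectal cancer",
                variants=_scoring_rows(weights, truth.crc_causal, genotypes, 0.0, rng),
            )
            path = os.path.join(out_dir, f"{pgs_id}.txt")
            _write_scoring_file(path, scoring)
            paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Catalog fixture


_BENIGN_TRAITS = [
    "type 2 diabetes",
    "body mass index",
    "coronary artery disease",
    "educational attainment",
    "hemorrhoids",
    "benign neoplasm of colon",  # precursor lesion: deliberately retained
    "rectal polyps",             # precursor lesion: deliberately retained
    "breast carcinoma",
    "smoking status",
    "inflammatory bowel disease",
]
_CRC_TRAITS = ["colorectal cancer", "colon cancer", "rectal cancer"]
_BROAD_TRAITS = ["gastrointestinal cancer", "rectal/anal cancer", "gastrointestinal cancer"]

FIXTURE_STRATA = {"no_overlap": 9, "high_missingness": 485, "crc_trait": 40,
                  "broad_crc_trait": 3, "kept": 2187}
_FIXTURE_VARIANTS_PER_SCORE = 20


def _fixture_entry(
    pgs_id: str, trait: str, n_matched: int, panel_positions: np.ndarray,
    rng: np.random.Generator,
) -> ScoringFile:
    nv = _FIXTURE_VARIANTS_PER_SCORE
    chosen = rng.choice(panel_positions, size=n_matched, replace=False)
    off = 10_000_000 + rng.choice(1_000_000, size=nv - n_matched, replace=False)
    variants = []
    for i, pos in enumerate(np.concatenate([chosen, off])):
        # half the matched entries are written in swapped orientation: the
        # orientation-free key must still match the panel
        if i % 2 == 0:
            ea, oa = "C", "A"
        else:
            ea, oa = "A", "C"
        variants.append(
            VariantRecord(
                variant_id=f"1:{int(pos)}",
                effect_allele=ea,
                other_allele=oa,
                effect_weight=float(np.round(rng.normal(0, 0.1), 6)),
            )
        )
    return ScoringFile(pgs_id=pgs_id, trait_label=trait, variants=variants)


def make_catalog_fixture(
    seed: int = 42, overlapping_strata: bool = False
) -> tuple[list[ScoringFile], set[str], CatalogFilterReport]:
    """Deterministic 2,724-entry catalog fixture plus its expected filter report.

    The entries fall in five mutually exclusive strata: 9 with zero panel
    overlap, 485 with overlap in [0.5, 0.8), 40 full-overlap entries with
    CRC/colon/rectal-cancer trait labels, 3 full-overlap entries with the
    broader gastrointestinal / rectal-anal labels, and 2,187 passing
    entries with overlap in (0.8, 1.0]. Returns (catalog, variant_index,
    expected_report).

    With ``overlapping_strata`` the CRC-labelled entries are additionally
    given high missingness, so the first-applicable-reason rule is what
    decides their reason code (high_missingness, not crc_trait).
    """
    rng = np.random.default_rng(seed)
    panel_positions = np.arange(1, 2001) * 10  # 2,000 panel variants
    variant_index = {variant_key("1", int(p), "A", "C") for p in panel_positions}
    nv = _FIXTURE_VARIANTS_PER_SCORE

    catalog: list[ScoringFile] = []
    expected = CatalogFilterReport()
    counter = 0

    def add(trait: str, n_matched: int, reason: str | None) -> None:
        nonlocal counter
        pgs_id = f"PGS{counter:06d}"
        counter += 1
        entry = _fixture_entry(pgs_id, trait, n_matched, panel_positions, rng)
        catalog.append(entry)
        expected.overlap_fraction[pgs_id] = n_matched / nv
        if reason is None:
            expected.kept.append(pgs_id)
        else:
            expected.excluded[pgs_id] = reason

    for i in range(FIXTURE_STRATA["no_overlap"]):
        add(_BENIGN_TRAITS[i % len(_BENIGN_TRAITS)], 0, "no_overlap")
    for i in range(FIXTURE_STRATA["high_missingness"]):
        add(_BENIGN_TRAITS[i % len(_BENIGN_TRAITS)], 10 + i % 6, "high_missingness")
    for i in range(FIXTURE_STRATA["crc_trait"]):
        if overlapping_strata:
            add(_CRC_TRAITS[i % 3], 10 + i % 6, "high_missingness")
        else:
            add(_CRC_TRAITS[i % 3], nv, "crc_trait")
    for i in range(FIXTURE_STRATA["broad_crc_trait"]):
        add(_BROAD_TRAITS[i], nv, "broad_crc_trait")
    for i in range(FIXTURE_STRATA["kept"]):
        add(_BENIGN_TRAITS[i % len(_BENIGN_TRAITS)], 17 + i % 4, None)

    return catalog, variant_index, expected


# ---------------------------------------------------------------------------
# On-disk cohort formats


def write_phenotype_tsv(
    phenotypes: list[PhenotypeRecord], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {
            "individual_id": [p.individual_id for p in phenotypes],
            "age": [p.age for p in phenotypes],
            "sex": [p.sex for p in phenotypes],
            "platform": [p.platform for p in phenotypes],
            "status": [p.status for p in phenotypes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path: str | os.PathLike) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    return [
        PhenotypeRecord(
            individual_id=row.individual_id,
            age=float(row.age),
            sex=str(row.sex),
            platform=str(row.platform),
            status=str(row.status),
        )
        for row in df.itertuples(index=False)
    ]


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Minimal uncompressed VCF with a DS (dosage) FORMAT field."""
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        order = np.argsort(genotypes.position, kind="stable")
        for j in order:
            d = genotypes.dosages[:, j]
            vals = "\t".join("." if np.isnan(x) else f"{x:g}" for x in d)
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.position[j]}\t.\t"
                f"{genotypes.ref[j]}\t{genotypes.alt[j]}\t.\tPASS\t.\tDS\t{vals}\n"
            )
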