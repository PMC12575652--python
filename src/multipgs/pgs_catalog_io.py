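"""Reading PGS-Catalog-format scoring files and catalog-level QC filtering.

A scoring file is a tab-separated table of variant weights, preceded by
``#``-prefixed metadata lines (``#trait_reported=...`` etc.). Each row gives
a variant (rsID and/or chromosome:position), its effect and other allele,
and the per-allele effect weight. A *catalog* is simply a list of such
files; before any score is computed the catalog is reduced by an exclusion
cascade: scores with no variant overlap with the genotype panel, scores
with too many missing variants, and scores for the target disease itself
(or traits that subsume it) are removed, in that order.
"""

from __future__ import annotations

import gzip
import io
import os
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "VariantRecord",
    "ScoringFile",
    "CatalogFilterReport",
    "variant_key",
    "parse_scoring_file",
    "compute_overlap",
    "filter_catalog",
    "DEFAULT_EXCLUDED_TRAITS",
    "DEFAULT_BROAD_EXCLUDED_TRAITS",
    "write_filter_report",
]

# Trait exclusion defaults: scores that predict the target outcome itself,
# and broader traits whose case sets subsume many colorectal-cancer cases.
# Matching is case-insensitive substring matching on the reported trait.
DEFAULT_EXCLUDED_TRAITS = ["colorectal cancer", "colon cancer", "rectal cancer"]
DEFAULT_BROAD_EXCLUDED_TRAITS = ["gastrointestinal cancer", "rectal/anal cancer"]

_MANDATORY_COLUMNS = ("effect_allele", "effect_weight")


class ScoringFileFormatError(ValueError):
    """Raised when a scoring file lacks mandatory structure."""


class ScoringFileContentError(ValueError):
    """Raised when a scoring file parses but yields no usable variants."""


@dataclass(frozen=True)
class VariantRecord:
    """One weighted variant of a polygenic score.

    ``variant_id`` is a ``chromosome:position`` string when positional
    information is available, otherwise the rsID. ``effect_weight`` is the
    per-allele weight (log odds ratio or beta) applied to the effect-allele
    dosage.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    effect_weight: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"effect and other allele identical ({self.effect_allele}) "
                f"for variant {self.variant_id}"
            )

    @property
    def key(self) -> str:
        """Orientation-free matching key: chrom:pos:sorted allele pair."""
        a, b = sorted((self.effect_allele, self.other_allele))
        return f"{self.variant_id}:{a}:{b}"


@dataclass
class ScoringFile:
    """A published polygenic score: identifier, trait label, variant weights."""

    pgs_id: str
    trait_label: str
    variants: list[VariantRecord]
    dropped_count: int = 0

    def __len__(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]


@dataclass
class CatalogFilterReport:
    """Outcome of the exclusion cascade over a catalog of scoring files.

    ``excluded`` maps pgs_id to the first applicable reason code among
    ``no_overlap``, ``high_missingness``, ``crc_trait``, ``broad_crc_trait``.
    """

    kept: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)
    overlap_fraction: dict[str, float] = field(default_factory=dict)

    def reason_counts(self) -> dict[str, int]:
        counts = {
            "no_overlap": 0,
            "high_missingness": 0,
            "crc_trait": 0,
            "broad_crc_trait": 0,
        }
        for reason in self.excluded.values():
            counts[reason] += 1
        return counts


def variant_key(chrom: str | int, position: int, allele_a: str, allele_b: str) -> str:
    """Build the canonical variant key used for score/genotype matching."""
    a, b = sorted((str(allele_a), str(allele_b)))
    return f"{chrom}:{position}:{a}:{b}"


def _open_text(path: str | os.PathLike) -> io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_scoring_file(path: str | os.PathLike) -> ScoringFile:
    """Parse one PGS-Catalog-dialect scoring file.

    Metadata lines begin with ``#``; ``#pgs_id=`` and ``#trait_reported=``
    are honoured when present (pgs_id falls back to the file stem). The
    header must name at least ``effect_allele`` and ``effect_weight``.
    Rows whose weight does not parse as a finite number are dropped and
    counted in ``dropped_count``.
    """
    metadata: dict[str, str] = {}
    with _open_text(path) as fh:
        pos = 0
        while True:
            line = fh.readline()
            if not line:
                break
            if line.startswith("#"):
                m = re.match(r"#\s*([\w.]+)\s*=\s*(.*)", line.strip())
                if m:
                    metadata[m.group(1)] = m.group(2).strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        table = pd.read_csv(fh, sep="\t", dtype=str)

    for col in _MANDATORY_COLUMNS:
        if col not in table.columns:
            raise ScoringFileFormatError(
                f"{path}: mandatory column '{col}' missing from header "
                f"(found: {list(table.columns)})"
            )

    def _to_float(token):  # Python float() is correctly rounded; to_numeric is not
        try:
            return float(token)
        except (TypeError, ValueError):
            return float("nan")

    weights = table["effect_weight"].map(_to_float)
    ok = weights.notna() & ~weights.isin([float("inf"), float("-inf")])
    dropped = int((~ok).sum())
    table = table.loc[ok]
    weights = weights.loc[ok]

    has_pos = "chr_name" in table.columns and "chr_position" in table.columns
    variants: list[VariantRecord] = []
    for i, row in enumerate(table.itertuples(index=False)):
        rowd = dict(zip(table.columns, row))
        if has_pos and pd.notna(rowd["chr_name"]) and pd.notna(rowd["chr_position"]):
            vid = f"{rowd['chr_name']}:{rowd['chr_position']}"
        elif "rsID" in table.columns and pd.notna(rowd.get("rsID")):
            vid = str(rowd["rsID"])
        else:
            raise ScoringFileFormatError(
                f"{path}: no positional columns (chr_name/chr_position) or rsID"
            )
        other = rowd.get("other_allele")
        variants.append(
            VariantRecord(
                variant_id=vid,
                effect_allele=str(rowd["effect_allele"]),
                other_allele="" if pd.isna(other) else str(other),
                effect_weight=float(weights.iloc[i]),
            )
        )

    if not variants:
        raise ScoringFileContentError(f"{path}: no parseable variant rows")

    stem = os.path.basename(os.fspath(path))
    for suffix in (".gz", ".txt", ".tsv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return ScoringFile(
        pgs_id=metadata.get("pgs_id", stem),
        trait_label=metadata.get("trait_reported", ""),
        variants=variants,
        dropped_count=dropped,
    )


def compute_overlap(scoring: ScoringFile, variant_index: set[str]) -> float:
    """Fraction of a score's variants present in a genotype variant index.

    Keys are ``chrom:pos:sortedalleles``, so a variant whose effect/other
    alleles are swapped relative to the genotype panel's ref/alt still
    matches (orientation is resolved later, at scoring time).
    """
    if not scoring.variants:
        return 0.0
    if not variant_index:
        return 0.0
    matched = sum(1 for v in scoring.variants if v.key in variant_index)
    return matched / len(scoring.variants)


def _trait_matches(label: str, patterns: list[str]) -> bool:
    low = label.lower()
    return any(p.lower() in low for p in patterns)


def filter_catalog(
    catalog: list[ScoringFile],
    variant_index: set[str],
    missingness_threshold: float = 0.20,
    excluded_traits: list[str] | None = None,
    broad_excluded_traits: list[str] | None = None,
) -> CatalogFilterReport:
    """Apply the exclusion cascade to a catalog of candidate scores.

    Cascade order, each score receiving the first applicable reason:

    1. ``no_overlap`` — zero variants in common with the genotype index;
    2. ``high_missingness`` — overlap below ``1 - missingness_threshold``
       (strictly: a score with exactly the threshold present is kept);
    3. ``crc_trait`` — trait label matches the target-disease patterns;
    4. ``broad_crc_trait`` — trait label matches the broader patterns.

    Scores for precursor lesions (benign colon neoplasms, rectal polyps)
    are deliberately not in the default pattern lists and are retained.
    """
    if excluded_traits is None:
        excluded_traits = DEFAULT_EXCLUDED_TRAITS
    if broad_excluded_traits is None:
        broad_excluded_traits = DEFAULT_BROAD_EXCLUDED_TRAITS

    report = CatalogFilterReport()
    for scoring in catalog:
        frac = compute_overlap(scoring, variant_index)
        report.overlap_fraction[scoring.pgs_id] = frac
        if frac == 0.0:
            report.excluded[scoring.pgs_id] = "no_overlap"
        elif frac < 1.0 - missingness_threshold:
            report.excluded[scoring.pgs_id] = "high_missingness"
        elif _trait_matches(scoring.trait_label, excluded_traits):
            report.excluded[scoring.pgs_id] = "crc_trait"
        elif _trait_matches(scoring.trait_label, broad_excluded_traits):
            report.excluded[scoring.pgs_id] = "broad_crc_trait"
        else:
            report.kept.append(scoring.pgs_id)
    return report


def write_filter_report(
    report: CatalogFilterReport, catalog: list[ScoringFile], path: str | os.PathLike
) -> None:
    """Write the cascade outcome as a TSV: one row per catalog entry."""
    rows = []
    for scoring in catalog:
        pid = scoring.pgs_id
        excluded = pid in report.excluded
        rows.append(
            {
                "pgs_id": pid,
                "trait_label": scoring.trait_label,
                "n_variants": len(scoring),
                "overlap_fraction": report.overlap_fraction.get(pid, float("nan")),
                "status": "excluded" if excluded else "kept",
                "reason": report.excluded.get(pid, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
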