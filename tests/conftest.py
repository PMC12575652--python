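"""Shared fixtures: small deterministic cohorts and scoring files."""

import numpy as np
import pandas as pd
import pytest

from multipgs import (
    GenotypeMatrix,
    ScoringFile,
    SimulationConfig,
    VariantRecord,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale simulation config used across module tests."""
    return SimulationConfig(
        n_individuals=2_000,
        m_variants=200,
        n_causal=40,
        n_traits=6,
        shared_causal_fraction=(0.5, 0.5, 0.5, 0, 0, 0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(genotypes, truth, phenotypes) for the small config."""
    return simulate_cohort(small_config)


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """Four individuals x three hand-written variants, one missing entry."""
    return GenotypeMatrix(
        individual_ids=["a", "b", "c", "d"],
        chrom=np.array(["1", "1", "2"], dtype=object),
        position=np.array([100, 200, 300]),
        ref=np.array(["A", "A", "T"], dtype=object),
        alt=np.array(["G", "G", "C"], dtype=object),
        dosages=np.array(
            [
                [2.0, 0.0, 1.0],
                [1.0, 1.0, 0.0],
                [0.0, 2.0, np.nan],
                [2.0, 2.0, 2.0],
            ]
        ),
    )


@pytest.fixture
def toy_scoring() -> ScoringFile:
    """Three variants matching toy_genotypes; the second one swapped."""
    return ScoringFile(
        pgs_id="PGS_TOY",
        trait_label="type 2 diabetes",
        variants=[
            VariantRecord("1:100", "G", "A", 0.5),
            VariantRecord("1:200", "A", "G", -0.25),
            VariantRecord("2:300", "C", "T", 1.0),
        ],
    )


def write_scoring_text(path, rows, trait="some trait", pgs_id="PGS_TXT"):
    """Helper: write a scoring file from (chr, pos, ea, oa, weight) tuples."""
    with open(path, "wt") as fh:
        fh.write(f"#pgs_id={pgs_id}\n#trait_reported={trait}\n")
        fh.write("rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n")
        for i, (c, p, ea, oa, w) in enumerate(rows):
            fh.write(f"rs{i}\t{c}\t{p}\t{ea}\t{oa}\t{w}\n")
    return path
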