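"""Generator contracts: HWE genotypes, pleiotropic weights, liability model,
scoring-file emission, and the catalog fixture."""

import dataclasses

import numpy as np
import pytest

from multipgs import (
    SimulationConfig,
    compute_overlap,
    filter_catalog,
    make_catalog_fixture,
    parse_scoring_file,
    simulate_cohort,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_trait_weights,
)
from multipgs.cadj_auc import LabeledScores, empirical_auc
from multipgs.synthetic_data import emit_scoring_files


class TestSimulateGenotypes:
    def test_forced_half_maf_mean_dosage(self):
        cfg = SimulationConfig(
            n_individuals=50_000, m_variants=1, n_causal=1, n_traits=1,
            shared_causal_fraction=(0.5,), maf_range=(0.5, 0.5), seed=1,
        )
        geno = simulate_genotypes(cfg)
        assert 0.98 <= geno.dosages.mean() <= 1.02

    def test_reproducible_and_integer_valued(self):
        cfg = SimulationConfig(n_individuals=200, m_variants=50, n_causal=10,
                               n_traits=1, shared_causal_fraction=(0.5,), seed=2)
        g1, g2 = simulate_genotypes(cfg), simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert set(np.unique(g1.dosages)) <= {0.0, 1.0, 2.0}

    def test_allele_frequencies_recover_mafs(self):
        cfg = SimulationConfig(n_individuals=20_000, m_variants=100, n_causal=10,
                               n_traits=1, shared_causal_fraction=(0.0,), seed=3)
        geno = simulate_genotypes(cfg)
        from multipgs.synthetic_data import _draw_mafs

        mafs = _draw_mafs(cfg)
        freqs = geno.dosages.mean(axis=0) / 2
        # binomial sampling error at n=20,000: generous 4-sigma band
        se = np.sqrt(mafs * (1 - mafs) / (2 * cfg.n_individuals))
        assert np.all(np.abs(freqs - mafs) < 4.5 * se + 1e-12)

    def test_replicates_share_universe_but_differ(self):
        cfg = SimulationConfig(n_individuals=100, m_variants=50, n_causal=10,
                               n_traits=1, shared_causal_fraction=(0.5,), seed=4)
        g0, g1 = simulate_genotypes(cfg, 0), simulate_genotypes(cfg, 1)
        assert list(g0.position) == list(g1.position)
        assert not np.array_equal(g0.dosages, g1.dosages)


class TestSimulateTraitWeights:
    def test_full_sharing_no_noise_duplicates_crc_weights(self):
        cfg = SimulationConfig(n_individuals=10, m_variants=200, n_causal=50,
                               n_traits=2, shared_causal_fraction=(1.0, 1.0),
                               weight_noise_sd=0.0, seed=5)
        _, truth = simulate_trait_weights(cfg)
        for k in range(2):
            idx = truth.trait_causal[k]
            r = np.corrcoef(truth.trait_weights[k, idx], truth.crc_weights[idx])[0, 1]
            assert abs(r) > 0.99

    def test_zero_sharing_gives_uncorrelated_scores(self):
        cfg = SimulationConfig(n_individuals=10_000, m_variants=400, n_causal=80,
                               n_traits=1, shared_causal_fraction=(0.0,),
                               weight_noise_sd=0.0, seed=6)
        geno = simulate_genotypes(cfg)
        _, truth = simulate_trait_weights(cfg)
        trait_prs = geno.dosages @ truth.trait_weights[0]
        crc_g = geno.dosages @ truth.crc_weights
        r = np.corrcoef(trait_prs, crc_g)[0, 1]
        assert abs(r) < 0.05

    def test_genetic_variance_matches_heritability(self):
        cfg = SimulationConfig(n_individuals=10_000, m_variants=1_000, n_causal=100,
                               n_traits=1, shared_causal_fraction=(0.5,), seed=7)
        geno = simulate_genotypes(cfg)
        _, truth = simulate_trait_weights(cfg)
        g = (geno.dosages - 2 * truth.mafs) @ truth.crc_weights
        assert g.var(ddof=1) == pytest.approx(cfg.h2_liability, rel=0.10)


class TestSimulatePhenotypes:
    def test_status_frequencies_follow_thresholds(self):
        cfg = SimulationConfig(
            n_individuals=100_000, m_variants=20, n_causal=5, n_traits=1,
            shared_causal_fraction=(0.5,), h2_liability=0.0,
            age_effect=0.0, sex_effect=0.0,
            crc_threshold_quantile=0.95, aa_band_quantile=0.90, seed=8,
        )
        geno, truth, phen = simulate_cohort(cfg)
        counts = {"crc": 0, "advanced_adenoma": 0, "control": 0}
        for p in phen:
            counts[p.status] += 1
        n = cfg.n_individuals
        assert counts["crc"] / n == pytest.approx(0.05, abs=0.01)
        assert counts["advanced_adenoma"] / n == pytest.approx(0.05, abs=0.01)
        assert counts["control"] / n == pytest.approx(0.90, abs=0.01)

    def test_true_genetic_value_auc_matches_monte_carlo_oracle(self):
        cfg = SimulationConfig(n_individuals=30_000, m_variants=500, n_causal=100,
                               n_traits=1, shared_causal_fraction=(0.5,),
                               age_effect=0.0, sex_effect=0.0, seed=9)
        geno, truth, phen = simulate_cohort(cfg)
        labels = np.array([1 if p.status == "crc" else 0 for p in phen])
        keep = np.array([p.status != "advanced_adenoma" for p in phen])
        import pandas as pd

        auc_sim = empirical_auc(
            LabeledScores(truth.genetic_value[keep], labels[keep],
                          pd.DataFrame(index=range(int(keep.sum()))))
        )

        # independent Monte-Carlo oracle from the liability model itself
        rng = np.random.default_rng(1234)
        n_mc = 2_000_000
        g = rng.normal(0, np.sqrt(cfg.h2_liability), n_mc)
        liab = g + rng.normal(0, np.sqrt(1 - cfg.h2_liability), n_mc)
        crc_cut = np.quantile(liab, cfg.crc_threshold_quantile)
        aa_cut = np.quantile(liab, cfg.aa_band_quantile)
        is_crc = liab > crc_cut
        is_ctrl = liab <= aa_cut
        scores = np.concatenate([g[is_crc], g[is_ctrl]])
        lab = np.concatenate([np.ones(is_crc.sum(), int), np.zeros(is_ctrl.sum(), int)])
        auc_mc = empirical_auc(LabeledScores(scores, lab, pd.DataFrame(index=range(len(lab)))))
        assert auc_sim == pytest.approx(auc_mc, abs=0.01)

    def test_same_seed_reproduces_statuses(self):
        cfg = SimulationConfig(n_individuals=500, m_variants=50, n_causal=10,
                               n_traits=1, shared_causal_fraction=(0.5,), seed=10)
        _, _, p1 = simulate_cohort(cfg)
        _, _, p2 = simulate_cohort(cfg)
        assert [p.status for p in p1] == [q.status for q in p2]

    def test_age_band_and_sex_balance(self, small_cohort):
        _, _, phen = small_cohort
        ages = np.array([p.age for p in phen])
        assert ages.min() >= 40 and ages.max() <= 90
        frac_male = np.mean([p.sex == "male" for p in phen])
        assert 0.45 < frac_male < 0.55


class TestEmitScoringFiles:
    def test_zero_missingness_full_overlap(self, small_cohort, tmp_path):
        geno, truth, _ = small_cohort
        paths = emit_scoring_files(truth, geno, tmp_path, missingness=0.0, seed=1)
        for path in paths:
            sf = parse_scoring_file(path)
            assert compute_overlap(sf, geno.variant_index()) == 1.0

    def test_quarter_missingness_gives_three_quarters_overlap(self, small_cohort, tmp_path):
        geno, truth, _ = small_cohort
        paths = emit_scoring_files(
            truth, geno, tmp_path, missingness=0.25, include_crc_files=False, seed=2
        )
        n_var = len(truth.trait_causal[0])
        for path in paths:
            sf = parse_scoring_file(path)
            got = compute_overlap(sf, geno.variant_index())
            assert got == pytest.approx(0.75, abs=1.0 / n_var)

    def test_weights_round_trip_exactly(self, small_cohort, tmp_path):
        geno, truth, _ = small_cohort
        paths = emit_scoring_files(truth, geno, tmp_path, missingness=0.0,
                                   include_crc_files=False, seed=3)
        sf = parse_scoring_file(paths[0])
        causal = truth.trait_causal[0]
        np.testing.assert_array_equal(
            [v.effect_weight for v in sf.variants],
            truth.published_trait_weights[0, causal],
        )

    def test_crc_files_present_with_crc_trait_label(self, small_cohort, tmp_path):
        geno, truth, _ = small_cohort
        paths = emit_scoring_files(truth, geno, tmp_path, seed=4)
        by_id = {parse_scoring_file(p).pgs_id: parse_scoring_file(p) for p in paths}
        assert {"CRC-KL200", "CRC-LDpred"} <= set(by_id)
        assert by_id["CRC-KL200"].trait_label == "colorectal cancer"


class TestCatalogFixture:
    def test_expected_report_matches_filter(self):
        catalog, idx, expected = make_catalog_fixture(seed=42)
        assert len(catalog) == 2724
        rep = filter_catalog(catalog, idx)
        assert rep.kept == expected.kept
        assert rep.excluded == expected.excluded

    def test_regeneration_is_identical(self):
        c1, i1, e1 = make_catalog_fixture(seed=42)
        c2, i2, e2 = make_catalog_fixture(seed=42)
        assert i1 == i2 and e1.kept == e2.kept
        for a, b in zip(c1, c2):
            assert a.pgs_id == b.pgs_id and a.trait_label == b.trait_label
            assert a.variants == b.variants
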