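"""Synthetic-study generator: determinism, planted effects, latent recovery."""

import numpy as np
import pandas as pd
import pytest

from metaboqtl.errors import ConfigError
from metaboqtl.phenotypes import derive_feed_phenotypes
from metaboqtl.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_covariates,
    simulate_feed_records,
    simulate_gene_sets,
    simulate_genotypes,
    simulate_metabolites,
    simulate_study,
    snp_effect_for_variance_fraction,
    trait_effect_for_variance_fraction,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.3, 0.2)},
            {"maf_range": (0.1, 0.6)},
            {"metabolite_h2": 1.0},
            {"metabolite_h2": -0.1},
            {"n_animals": 1},
            {"days_on_test": 10},
            {"causal_plan": [(0, 10_000, 1.0)]},
            {"trait_plan": [("weight", 0, 1.0)]},
        ],
    )
    def test_invalid_configs_raise(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(n_snps=100, **kwargs)


class TestGenotypes:
    def test_fixed_seed_is_bitwise_reproducible(self, small_config):
        a = simulate_genotypes(small_config)
        b = simulate_genotypes(small_config)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snps.equals(b.snps)

    def test_dosages_in_codomain(self):
        cfg = SimulationConfig(n_animals=4, n_snps=3, seed=9)
        geno = simulate_genotypes(cfg)
        assert set(np.unique(geno.dosages)) <= {0.0, 1.0, 2.0}

    def test_half_frequency_symmetry(self):
        cfg = SimulationConfig(
            n_animals=2000, n_snps=50, maf_range=(0.5, 0.5), seed=3
        )
        geno = simulate_genotypes(cfg)
        freqs = geno.allele_frequencies()
        # binomial SE at p=0.5, 2n=4000 draws is ~0.008
        assert np.all(np.abs(freqs - 0.5) < 0.04)

    def test_positions_within_chromosomes_and_sorted(self, small_genotypes, small_config):
        snps = small_genotypes.snps
        assert set(snps["chrom"]) <= {str(c) for c in range(1, 6)}
        for _, sub in snps.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing
            assert (sub["pos"] >= 1).all()
            assert (sub["pos"] <= small_config.chromosome_length).all()

    def test_ld_mode_induces_adjacent_correlation(self):
        cfg = SimulationConfig(
            n_animals=800, n_snps=40, n_chromosomes=1, ld_rho=0.9,
            maf_range=(0.3, 0.5), seed=17,
        )
        geno = simulate_genotypes(cfg)
        r = np.corrcoef(geno.dosages.T)
        adjacent = np.diag(r, k=1).mean()
        cfg0 = SimulationConfig(
            n_animals=800, n_snps=40, n_chromosomes=1, ld_rho=0.0,
            maf_range=(0.3, 0.5), seed=17,
        )
        r0 = np.corrcoef(simulate_genotypes(cfg0).dosages.T)
        assert adjacent > 0.3 > abs(np.diag(r0, k=1).mean())


class TestCovariates:
    def test_breed_fractions_form_simplex(self, small_covariates):
        frac = small_covariates[[f"breed{k}" for k in range(1, 7)]].to_numpy()
        assert np.allclose(frac.sum(axis=1), 1.0, atol=1e-9)
        assert (frac >= 0).all()

    def test_expected_levels_present(self, small_covariates):
        assert set(small_covariates["animal_type"]) <= {"bull", "heifer", "steer"}
        assert small_covariates["birth_year"].between(2002, 2011).all()


class TestMetabolites:
    def test_null_model_is_gaussian_noise_around_baseline(self):
        cfg = SimulationConfig(
            n_animals=3000, n_snps=50, n_metabolites=2, metabolite_h2=0.0, seed=21
        )
        geno = simulate_genotypes(cfg)
        metab, truth = simulate_metabolites(geno, cfg)
        v = metab["metab_1"].to_numpy()
        assert v.mean() == pytest.approx(cfg.metabolite_baseline, abs=1.0)
        assert v.std(ddof=1) == pytest.approx(cfg.metabolite_noise_sd, rel=0.1)
        assert np.allclose(truth.polygenic, 0.0)

    def test_causal_effect_shifts_dosage_groups_by_two_beta(self):
        cfg = SimulationConfig(
            n_animals=6000, n_snps=20, n_metabolites=1, metabolite_h2=0.0,
            metabolite_noise_sd=1e-9, causal_plan=[(0, 4, 3.0)], seed=22,
        )
        geno = simulate_genotypes(cfg)
        metab, _ = simulate_metabolites(geno, cfg)
        y = metab["metab_1"].to_numpy()
        d = geno.dosages[:, 4]
        assert y[d == 2].mean() - y[d == 0].mean() == pytest.approx(6.0, abs=1e-6)

    def test_causal_snp_survives_generator_maf_bounds(self):
        cfg = SimulationConfig(
            n_animals=500, n_snps=100, n_metabolites=1,
            causal_plan=[(0, 7, 1.0)], seed=23,
        )
        geno = simulate_genotypes(cfg)
        _, truth = simulate_metabolites(geno, cfg)
        snp_id = truth.causal_snp_ids["metab_1"][0]
        j = geno.snps.index[geno.snps["id"] == snp_id][0]
        maf = geno.minor_allele_frequencies()[j]
        assert maf >= 0.02  # drawn from maf_range (0.05, 0.5) +/- sampling

    def test_effect_size_helper_yields_target_fraction(self):
        beta = snp_effect_for_variance_fraction(0.05, 0.3, 100.0)
        v_snp = 2 * 0.3 * 0.7 * beta**2
        assert v_snp / (v_snp + 100.0) == pytest.approx(0.05, rel=1e-10)


class TestFeedRecords:
    def test_noise_free_records_recover_latents_exactly(self):
        cfg = SimulationConfig(
            n_animals=30, n_snps=20, n_metabolites=1,
            bw_noise_sd=0.0, dmi_noise_sd=0.0, seed=31,
        )
        study_geno = simulate_genotypes(cfg)
        metab, truth = simulate_metabolites(study_geno, cfg)
        weights, intake = simulate_feed_records(metab, cfg, truth)
        pheno = derive_feed_phenotypes(weights, intake)
        pheno = pheno.set_index("animal").loc[metab["animal"]]
        assert np.allclose(pheno["adg"], truth.latent_adg, atol=1e-8)
        assert np.allclose(pheno["initial_bw"], truth.latent_initial_bw, atol=1e-6)
        # DMI exactly linear in ADG and MWT -> RFI identically zero
        assert np.allclose(pheno["rfi"], 0.0, atol=1e-8)

    def test_planted_rfi_effect_recovered_by_regression(self):
        # large n so the regression SE is small relative to the effect
        cfg0 = SimulationConfig(
            n_animals=4000, n_snps=10, n_metabolites=1, metabolite_h2=0.0, seed=32
        )
        b = trait_effect_for_variance_fraction(
            0.05, cfg0.metabolite_noise_sd**2, cfg0.dmi_noise_sd**2
        )
        cfg = SimulationConfig(
            n_animals=4000, n_snps=10, n_metabolites=1, metabolite_h2=0.0,
            trait_plan=[("rfi", 0, b)], seed=32,
        )
        geno = simulate_genotypes(cfg)
        metab, truth = simulate_metabolites(geno, cfg)
        weights, intake = simulate_feed_records(metab, cfg, truth)
        pheno = derive_feed_phenotypes(weights, intake).set_index("animal")
        pheno = pheno.loc[metab["animal"]]
        x = metab["metab_1"].to_numpy()
        slope = np.polyfit(x, pheno["rfi"].to_numpy(), 1)[0]
        se = cfg.dmi_noise_sd / (np.sqrt(4000) * x.std())
        assert slope == pytest.approx(b, abs=4 * se)

    def test_weigh_grid_is_fortnightly(self):
        cfg = SimulationConfig(n_animals=5, n_snps=10, n_metabolites=1, seed=33)
        geno = simulate_genotypes(cfg)
        metab, truth = simulate_metabolites(geno, cfg)
        weights, _ = simulate_feed_records(metab, cfg, truth)
        days = sorted(weights["day"].unique())
        assert days[0] == 0 and days[-1] == cfg.days_on_test
        assert all(b - a <= 14 for a, b in zip(days, days[1:]))


class TestAnnotationAndSets:
    def test_planted_genes_cover_causal_snps(self):
        cfg = SimulationConfig(
            n_animals=20, n_snps=50, n_chromosomes=2, n_metabolites=2,
            causal_plan=[(0, 3, 1.0), (1, 40, 1.0)], seed=41,
        )
        study = simulate_study(cfg)
        for metab, genes in study.truth.planted_genes.items():
            for gid in genes:
                row = study.annotation[study.annotation["gene_id"] == gid].iloc[0]
                snp_ids = study.truth.causal_snp_ids[metab]
                snp = study.genotypes.snps.set_index("id").loc[snp_ids[0]]
                assert row["chrom"] == snp["chrom"]
                assert row["start"] <= snp["pos"] <= row["end"]

    def test_gene_sets_reference_annotation_and_include_planted_set(self):
        cfg = SimulationConfig(
            n_animals=20, n_snps=50, n_metabolites=1,
            causal_plan=[(0, 3, 1.0)], seed=42,
        )
        study = simulate_study(cfg)
        all_genes = set(study.annotation["gene_id"])
        for members in study.gene_sets.values():
            assert members <= all_genes
        planted = {g for gs in study.truth.planted_genes.values() for g in gs}
        assert planted <= study.gene_sets["planted_function"]


def test_full_study_determinism():
    cfg = SimulationConfig(n_animals=40, n_snps=60, n_metabolites=2, seed=55)
    s1, s2 = simulate_study(cfg), simulate_study(cfg)
    assert np.array_equal(s1.genotypes.dosages, s2.genotypes.dosages)
    assert s1.metabolites.equals(s2.metabolites)
    assert s1.serial_weights.equals(s2.serial_weights)
    assert s1.covariates.equals(s2.covariates)
    assert s1.annotation.equals(s2.annotation)
    assert s1.gene_sets == s2.gene_sets
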