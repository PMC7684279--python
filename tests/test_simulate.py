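import hashlib
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from transprs.io import read_dosages, read_phenotypes, read_summary_stats
from transprs.qc import hwe_exact_test
from transprs.simulate import (Demographics, SimulationConfig, SmokingParams,
                               TrueEffects, liability_threshold,
                               marginal_linear_gwas, marginal_logistic_gwas,
                               simulate_discovery_cohort,
                               simulate_discovery_sumstats, simulate_effects,
                               simulate_genotypes, simulate_target_cohort,
                               variant_table)


def cfg(**kw):
    base = dict(n_variants=2_000, block_size=40, n_discovery=500,
                n_cases=40, n_relatives=16, n_controls=50, prevalence=0.1,
                seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"rg": 1.5}, {"rg": -1.0001}, {"within_block_rho": 1.0},
        {"prop_causal": 0.0}, {"h2_discovery": 1.0}, {"prevalence": 0.0},
        {"maf_range": (0.0, 0.5)}, {"maf_range": (0.2, 0.6)},
        {"n_relatives": 80, "n_cases": 40},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            cfg(**kw)


class TestEffects:
    def test_rg_zero_effects_uncorrelated(self):
        c = cfg(n_variants=5_000, prop_causal=1.0, rg=0.0)
        eff = simulate_effects(c)
        r = np.corrcoef(eff.beta_discovery, eff.beta_liability)[0, 1]
        assert abs(r) < 0.05

    def test_rg_one_effects_proportional(self):
        c = cfg(prop_causal=1.0, rg=1.0)
        eff = simulate_effects(c)
        r = np.corrcoef(eff.beta_discovery, eff.beta_liability)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_rg_recovered_across_seeds(self):
        # 2,000 causal variants per seed; Monte-Carlo se of the mean
        # correlation over 20 seeds is ~0.004
        rs = []
        for s in range(20):
            c = cfg(n_variants=4_000, prop_causal=0.5, rg=0.5, seed=s)
            eff = simulate_effects(c)
            caus = eff.causal
            rs.append(np.corrcoef(eff.beta_discovery[caus],
                                  eff.beta_liability[caus])[0, 1])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.02)

    def test_genetic_variance_scaled_to_h2(self):
        c = cfg(h2_discovery=0.37)
        eff = simulate_effects(c)
        p = variant_table(c)["maf"].to_numpy()
        var = np.sum(2 * p * (1 - p) * eff.beta_discovery ** 2)
        assert var == pytest.approx(0.37, rel=1e-9)

    def test_noncausal_effects_exactly_zero(self):
        eff = simulate_effects(cfg(prop_causal=0.1))
        assert np.all(eff.beta_discovery[~eff.causal] == 0.0)
        assert np.all(eff.beta_liability[~eff.causal] == 0.0)


class TestGenotypes:
    def test_no_ld_when_rho_zero(self):
        c = cfg(within_block_rho=0.0, n_variants=400, block_size=40)
        panel = simulate_genotypes(c, "discovery", n_samples=400)
        block = panel.dosages[:, :40]
        r = np.corrcoef(block.T)
        off = r[np.triu_indices(40, 1)]
        assert np.mean(off ** 2) < 0.01

    def test_ld_present_within_blocks(self):
        c = cfg(within_block_rho=0.8, n_variants=400, block_size=40)
        panel = simulate_genotypes(c, "discovery", n_samples=400)
        d = panel.dosages
        adjacent = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2
                    for j in range(0, 39)]
        assert np.mean(adjacent) > 0.15

    def test_sibling_genotype_correlation_near_half(self):
        rs = []
        for s in range(5):
            c = cfg(n_variants=1_000, seed=s)
            a, b = simulate_genotypes(c, "target-offspring", n_samples=400)
            for j in range(0, 1_000, 25):
                x, y = a.dosages[:, j], b.dosages[:, j]
                if x.std() > 0 and y.std() > 0:
                    rs.append(np.corrcoef(x, y)[0, 1])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.03)

    def test_target_allele_frequencies_match_maf(self):
        c = cfg(maf_range=(0.3, 0.3), n_variants=500)
        panel = simulate_genotypes(c, "target-founder", n_samples=500)
        freqs = panel.allele_frequencies()
        assert freqs.mean() == pytest.approx(0.3, abs=0.01)
        # per-variant binomial 4-sigma band on 1,000 alleles
        se = np.sqrt(0.3 * 0.7 / 1_000)
        assert np.mean(np.abs(freqs - 0.3) < 4 * se) > 0.98

    def test_founders_in_hardy_weinberg(self):
        c = cfg(n_variants=1_000, seed=3)
        panel = simulate_genotypes(c, "discovery", n_samples=500)
        rej = 0
        for j in range(panel.n_variants):
            col = np.round(panel.dosages[:, j]).astype(int)
            counts = [(col == k).sum() for k in (0, 1, 2)]
            if hwe_exact_test(*counts) < 0.05:
                rej += 1
        # the exact test is conservative: rejection rate at or below the
        # nominal 5%, but clearly nonzero
        assert 0.005 < rej / panel.n_variants < 0.07

    def test_deterministic_given_seed(self):
        c = cfg()
        p1 = simulate_genotypes(c, "discovery")
        p2 = simulate_genotypes(c, "discovery")
        np.testing.assert_array_equal(p1.dosages, p2.dosages)


class TestMarginalGwas:
    def test_linear_matches_statsmodels_per_variant(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, size=(60, 5)).astype(float)
        y = rng.normal(size=60)
        beta, se, p, mono = marginal_linear_gwas(X, y)
        for j in range(5):
            fit = sm.OLS(y, sm.add_constant(X[:, j])).fit()
            assert beta[j] == pytest.approx(fit.params[1], rel=1e-9)
            assert p[j] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_logistic_matches_statsmodels_per_variant(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, size=(120, 5)).astype(float)
        y = (rng.random(120) < 0.4).astype(float)
        beta, se, p, mono = marginal_logistic_gwas(X, y)
        for j in range(5):
            fit = sm.Logit(y, sm.add_constant(X[:, j])).fit(disp=0)
            assert beta[j] == pytest.approx(fit.params[1], rel=1e-5, abs=1e-8)
            assert p[j] == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_monomorphic_variant_flagged(self):
        X = np.column_stack([np.ones(30), np.r_[np.zeros(15), np.ones(15)]])
        y = np.random.default_rng(8).normal(size=30)
        beta, se, p, mono = marginal_linear_gwas(X, y)
        assert mono[0] and not mono[1]
        assert beta[0] == 0.0 and p[0] == 1.0


class TestSumstats:
    def test_null_trait_p_values_uniform(self):
        fracs = []
        for s in range(10):
            c = cfg(h2_discovery=0.0, seed=s)
            eff = simulate_effects(c)
            panel, pheno, _ = simulate_discovery_cohort(c, eff)
            ss = simulate_discovery_sumstats(panel, eff, c, "initiation",
                                             phenotypes=pheno,
                                             representation_noise=False)
            fracs.append((ss["p_value"] < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.015)

    def test_large_effect_variant_survives_strictest_cutoff(self):
        c = cfg(n_variants=500, block_size=25, n_discovery=2_000,
                prop_causal=0.002, h2_discovery=0.5)
        eff = simulate_effects(c)  # single causal variant carries h2 = 0.5
        panel, pheno, _ = simulate_discovery_cohort(c, eff)
        ss = simulate_discovery_sumstats(panel, eff, c, "initiation",
                                         phenotypes=pheno,
                                         representation_noise=False)
        j = int(np.flatnonzero(eff.causal)[0])
        assert ss["p_value"].iloc[j] < 1e-4

    def test_zero_effects_give_mean_zero_estimates(self):
        means = []
        for s in range(5):
            c = cfg(h2_discovery=0.0, seed=100 + s)
            eff = simulate_effects(c)
            panel, pheno, _ = simulate_discovery_cohort(c, eff)
            ss = simulate_discovery_sumstats(panel, eff, c, "quantity",
                                             phenotypes=pheno,
                                             representation_noise=False)
            means.append(ss["weight"].mean())
        assert abs(np.mean(means)) < 0.05

    def test_sumstats_file_schema_roundtrip(self, tmp_path):
        from transprs.io import write_summary_stats
        c = cfg(seed=5)
        eff = simulate_effects(c)
        panel, pheno, _ = simulate_discovery_cohort(c, eff)
        ss = simulate_discovery_sumstats(panel, eff, c, "cessation",
                                         phenotypes=pheno)
        path = tmp_path / "ss.tsv"
        write_summary_stats(ss.drop(columns=["monomorphic"]), path)
        back = read_summary_stats(path)
        assert len(back) == c.n_variants
        np.testing.assert_allclose(back["weight"], ss["weight"], rtol=1e-4,
                                   atol=1e-6)


class TestTargetCohort:
    def test_prevalence_half_threshold_is_zero(self):
        assert liability_threshold(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_group_sizes_and_smoking_field_consistency(self):
        c = cfg(seed=2)
        panel, pheno, truth = simulate_target_cohort(c)
        assert pheno["group"].value_counts().to_dict() == {
            "HC": 50, "SCZ": 40, "FR": 16}
        never = pheno["ever_smoker"] == 0
        assert pheno.loc[never, ["age_initiation", "cpd",
                                 "current_smoker"]].isna().all().all()
        ever = pheno["ever_smoker"] == 1
        assert pheno.loc[ever, "age_initiation"].notna().all()

    def test_cases_exceed_liability_threshold(self):
        c = cfg(seed=2)
        _, pheno, truth = simulate_target_cohort(c)
        thr = liability_threshold(c.prevalence)
        scz = truth["group"] == "SCZ"
        assert (truth.loc[scz, "liability"] > thr).all()
        assert (truth.loc[~scz, "liability"] <= thr).all()

    def test_rg_zero_smoking_independent_of_case_status(self):
        c = cfg(rg=0.0, n_cases=60, n_controls=60, n_relatives=0, seed=4)
        _, pheno, truth = simulate_target_cohort(c)
        sub = pheno[pheno["group"].isin(["HC", "SCZ"])]
        r = np.corrcoef(sub["ever_smoker"],
                        (sub["group"] == "SCZ").astype(float))[0, 1]
        assert abs(r) < 3 / np.sqrt(len(sub))


class TestFixtureSet:
    def test_reproducible_checksums_and_manifest(self, tmp_path, small_config):
        from transprs.simulate import generate_fixture_set
        m1 = generate_fixture_set(small_config, tmp_path / "a")
        m2 = generate_fixture_set(small_config, tmp_path / "b")
        pd.testing.assert_frame_equal(m1, m2)
        assert (m1["path"].str.startswith("sumstats_")).sum() == 4

    def test_read_back_dimensions_match_config(self, fixture_dir,
                                               small_config):
        panel = read_dosages(fixture_dir / "target.dosage.tsv", "dosage-tsv")
        n_target = (small_config.n_cases + small_config.n_relatives
                    + small_config.n_controls)
        assert panel.dosages.shape == (n_target, small_config.n_variants)
        pheno = read_phenotypes(fixture_dir / "phenotypes.tsv")
        assert len(pheno) == n_target
        ss = read_summary_stats(fixture_dir / "sumstats_initiation.tsv")
        assert len(ss) == small_config.n_variants

    def test_vcf_and_tsv_dialects_agree(self, fixture_dir):
        tsv = read_dosages(fixture_dir / "target.dosage.tsv", "dosage-tsv")
        vcf = read_dosages(fixture_dir / "target.vcf", "vcf-dosage")
        assert tsv.samples == vcf.samples
        np.testing.assert_allclose(tsv.dosages, vcf.dosages, atol=1e-6)
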