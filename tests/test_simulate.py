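import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cqrmeta as cq
from cqrmeta.data import PhenotypeTable
from cqrmeta.errors import ValidationError


class TestVariantSpec:
    def test_maf_bounds(self):
        with pytest.raises(ValidationError):
            cq.VariantSpec("v", maf=0.0)
        with pytest.raises(ValidationError):
            cq.VariantSpec("v", maf=0.6)
        cq.VariantSpec("v", maf=0.5)  # boundary allowed

    def test_null_requires_zero_effects(self):
        with pytest.raises(ValidationError):
            cq.VariantSpec("v", maf=0.2, effect_model="null", beta=0.1)

    def test_unknown_model(self):
        with pytest.raises(ValidationError):
            cq.VariantSpec("v", maf=0.2, effect_model="additive")


class TestSimulateGenotypes:
    def test_half_maf_symmetry(self):
        # binomial(2, 0.5) puts 1/4, 1/2, 1/4 on the genotype classes
        g = cq.simulate_genotypes(40000, [cq.VariantSpec("v", maf=0.5)], seed=1)
        freqs = np.bincount(g.dosages[:, 0].astype(int), minlength=3) / 40000
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)

    def test_cohort_scale_maf_range_all_classes(self):
        # the null-SNP protocol MAF range, at full cohort scale
        variants = [cq.VariantSpec("lo", 0.05), cq.VariantSpec("hi", 0.45)]
        g = cq.simulate_genotypes(72985, variants, seed=2)
        for j in range(2):
            assert set(np.unique(g.dosages[:, j])) == {0.0, 1.0, 2.0}

    def test_allele_frequency_within_3_binomial_sd(self):
        n, maf = 10000, 0.1
        g = cq.simulate_genotypes(n, [cq.VariantSpec("v", maf)], seed=3)
        phat = g.dosages[:, 0].mean() / 2
        sd = np.sqrt(maf * (1 - maf) / (2 * n))
        assert abs(phat - maf) < 3 * sd

    @pytest.mark.parametrize("seed", [11, 12, 13, 14])
    def test_hwe_not_rejected(self, seed):
        maf = 0.3
        g = cq.simulate_genotypes(5000, [cq.VariantSpec("v", maf)], seed=seed)
        obs = np.bincount(g.dosages[:, 0].astype(int), minlength=3)
        exp = 5000 * np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        chi2 = np.sum((obs - exp) ** 2 / exp)
        assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_validation(self):
        with pytest.raises(ValidationError):
            cq.simulate_genotypes(0, [cq.VariantSpec("v", 0.2)], seed=1)
        with pytest.raises(ValidationError):
            cq.simulate_genotypes(10, [], seed=1)

    def test_seed_determinism(self):
        vs = [cq.VariantSpec("v", 0.2)]
        a = cq.simulate_genotypes(500, vs, seed=9)
        b = cq.simulate_genotypes(500, vs, seed=9)
        assert np.array_equal(a.dosages, b.dosages)


class TestSimulatePhenotype:
    def test_null_moments_match_targets(self):
        variants = [cq.VariantSpec(f"v{i}", 0.2) for i in range(3)]
        config = cq.SimulationConfig(20000, variants, seed=21)
        _, pheno = cq.simulate_cohort(config)
        y = pheno.trait
        assert abs(y.mean() - (-0.25)) < 4 * 2.67 / np.sqrt(20000)
        assert abs(y.std() - 2.67) < 4 * 2.67 / np.sqrt(2 * 20000)

    def test_location_zero_noise_limit(self):
        # as noise sd -> 0 the trait is deterministic and linear in g with
        # slope exactly beta (up to the mean-centering shift)
        variants = [cq.VariantSpec("v", 0.3, "location", beta=-0.5)]
        config = cq.SimulationConfig(
            500, variants, trait_sd=1e-12, with_age=False, with_sex=False,
            with_array=False, seed=22,
        )
        genos, pheno = cq.simulate_cohort(config)
        g = genos.dosages[:, 0]
        resid = pheno.trait - (-0.5) * g
        assert np.ptp(resid) < 1e-9  # constant: all variation is beta*g

    def test_location_scale_quantile_slope_oracle(self):
        beta, theta, sd, n = -0.2, 0.15, 2.67, 12000
        variants = [cq.VariantSpec("v", 0.3, "location_scale", beta=beta, theta=theta)]
        config = cq.SimulationConfig(
            n, variants, trait_sd=sd, with_age=False, with_sex=False,
            with_array=False, seed=23,
        )
        genos, pheno = cq.simulate_cohort(config)
        eff = cq.fit_cqr(
            pheno, genos.dosages[:, 0], grid=cq.QuantileGrid((0.9,)),
            se_method="asymptotic",
        )
        oracle = cq.quantile_slope_oracle(0.9, beta, sd, theta)
        assert abs(eff.betas[0] - oracle) < 3.5 * eff.ses[0]

    def test_null_trait_independent_of_genotype(self):
        variants = [cq.VariantSpec(f"v{i}", 0.3) for i in range(5)]
        config = cq.SimulationConfig(20000, variants, seed=24)
        genos, pheno = cq.simulate_cohort(config)
        y = pheno.trait
        for j in range(5):
            r = np.corrcoef(genos.dosages[:, j], y)[0, 1]
            assert abs(r) < 4 / np.sqrt(20000)

    def test_trait_quantum_rounds_to_grid(self):
        config = cq.SimulationConfig(
            1000, [cq.VariantSpec("v", 0.2)], trait_quantum=0.125, seed=25
        )
        _, pheno = cq.simulate_cohort(config)
        assert np.allclose(pheno.trait, np.round(pheno.trait / 0.125) * 0.125)

    def test_dimension_mismatch(self):
        genos = cq.simulate_genotypes(100, [cq.VariantSpec("v", 0.2)], seed=1)
        config = cq.SimulationConfig(200, [cq.VariantSpec("v", 0.2)], seed=1)
        with pytest.raises(ValidationError):
            cq.simulate_phenotype(genos, config)

    def test_cohort_determinism(self):
        config = cq.SimulationConfig(300, [cq.VariantSpec("v", 0.2)], seed=31)
        g1, p1 = cq.simulate_cohort(config)
        g2, p2 = cq.simulate_cohort(config)
        assert np.array_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(p1.df, p2.df)


class TestPermutePhenotype:
    def test_single_row_identity(self):
        pheno = PhenotypeTable(pd.DataFrame({"individual_id": ["a"], "trait": [1.5]}))
        out = cq.permute_phenotype(pheno, seed=1)
        assert out.trait.tolist() == [1.5]

    def test_multiset_preserved(self, plain_pheno):
        out = cq.permute_phenotype(plain_pheno, seed=2)
        assert np.array_equal(np.sort(out.trait), np.sort(plain_pheno.trait))

    def test_covariates_stay_attached(self):
        df = pd.DataFrame(
            {"individual_id": list("abcd"), "trait": [1.0, 2, 3, 4], "age": [40, 50, 60, 70]}
        )
        out = cq.permute_phenotype(PhenotypeTable(df), seed=3)
        assert out.df["age"].tolist() == [40, 50, 60, 70]
        assert out.df["individual_id"].tolist() == list("abcd")

    def test_empty_table_rejected(self):
        pheno = PhenotypeTable(pd.DataFrame({"individual_id": [], "trait": []}))
        with pytest.raises(ValidationError):
            cq.permute_phenotype(pheno, seed=1)

    def test_null_ols_rejection_rate(self):
        # Monte-Carlo oracle: OLS slope of permuted trait on genotype rejects
        # at ~ alpha = 0.05
        rng = np.random.default_rng(7)
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        pheno = PhenotypeTable(
            pd.DataFrame({"individual_id": [f"i{i}" for i in range(n)],
                          "trait": rng.standard_normal(n)})
        )
        hits = 0
        n_perm = 200
        for s in range(n_perm):
            perm = cq.permute_phenotype(pheno, seed=s)
            hits += cq.fit_ols(perm, g).p < 0.05
        lo, hi = stats.binom.interval(0.999, n_perm, 0.05)
        assert lo <= hits <= hi


class TestComputeAvmse:
    def test_stated_formula(self):
        assert cq.compute_avmse(-2.0, -1.0, -2.0, -1.0) == pytest.approx(-2.5)

    def test_all_zero(self):
        assert cq.compute_avmse(0.0, 0.0, 0.0, 0.0) == 0.0

    def test_hand_evaluated_asymmetric(self):
        # right eye: -1 + (-0.5)/2 = -1.25; left: -2 + 0 = -2; mean -1.625
        assert cq.compute_avmse(-1.0, -0.5, -2.0, 0.0) == pytest.approx(-1.625)

    def test_single_missing_eye_uses_other(self):
        assert cq.compute_avmse(np.nan, np.nan, -2.0, -1.0) == pytest.approx(-2.5)

    def test_both_missing_marks_exclusion(self):
        assert np.isnan(cq.compute_avmse(np.nan, np.nan, np.nan, np.nan))

    def test_vectorized(self):
        out = cq.compute_avmse(
            [-2.0, np.nan], [-1.0, np.nan], [-2.0, -1.0], [-1.0, 0.0]
        )
        assert np.allclose(out, [-2.5, -1.0])
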