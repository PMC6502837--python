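import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cqrmeta as cq
from cqrmeta.data import GenotypeMatrix, PhenotypeTable
from cqrmeta.errors import DegenerateDesignError, ValidationError
from cqrmeta.regression import check_loss


def make_genos(dosage_cols, variant_ids=None):
    dosages = np.column_stack(dosage_cols).astype(float)
    n, m = dosages.shape
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    return GenotypeMatrix(
        individual_ids=np.array([f"i{i}" for i in range(n)], dtype=object),
        variant_ids=np.array(variant_ids, dtype=object),
        dosages=dosages,
        effect_allele=np.array(["A"] * m, dtype=object),
        other_allele=np.array(["G"] * m, dtype=object),
    )


def make_pheno(trait, **cols):
    n = len(trait)
    return PhenotypeTable(
        pd.DataFrame({"individual_id": [f"i{i}" for i in range(n)], "trait": trait, **cols})
    )


class TestQuantileGrid:
    def test_named_grids(self):
        assert np.allclose(cq.QuantileGrid.named(9).array, np.arange(0.1, 0.95, 0.1))
        assert np.allclose(cq.QuantileGrid.named(19).array, np.arange(0.05, 0.975, 0.05))
        assert np.allclose(cq.QuantileGrid.named(10).array, np.arange(0.05, 0.975, 0.1))
        assert np.allclose(cq.QuantileGrid.named(5).array, np.arange(0.1, 0.95, 0.2))

    def test_validation(self):
        with pytest.raises(ValidationError):
            cq.QuantileGrid((0.2, 0.1))
        with pytest.raises(ValidationError):
            cq.QuantileGrid((0.0, 0.5))
        with pytest.raises(ValidationError):
            cq.QuantileGrid(())
        with pytest.raises(ValidationError):
            cq.QuantileGrid.named(7)


class TestOrientRiskAlleles:
    def test_positive_slope_flipped_and_negated(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, 500).astype(float)
        y = 0.5 * g + rng.standard_normal(500)
        genos = make_genos([g])
        pheno = make_pheno(y)
        before = cq.fit_ols(pheno, g).beta
        oriented = cq.orient_risk_alleles(genos, pheno)
        after = cq.fit_ols(pheno, oriented.dosages[:, 0]).beta
        assert before > 0
        assert np.array_equal(oriented.dosages[:, 0], 2.0 - g)
        assert after == pytest.approx(-before, abs=1e-12)  # closed-form sign flip
        assert oriented.effect_allele[0] == "G" and oriented.other_allele[0] == "A"
        assert oriented.flipped[0]

    def test_negative_slope_unchanged_idempotent(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, 500).astype(float)
        y = -0.5 * g + rng.standard_normal(500)
        genos = make_genos([g])
        pheno = make_pheno(y)
        once = cq.orient_risk_alleles(genos, pheno)
        twice = cq.orient_risk_alleles(once, pheno)
        assert np.array_equal(once.dosages, genos.dosages)
        assert np.array_equal(twice.dosages, once.dosages)
        assert not once.flipped[0]

    def test_monomorphic_flagged(self):
        genos = make_genos([np.ones(50)])
        pheno = make_pheno(np.random.default_rng(3).standard_normal(50))
        out = cq.orient_risk_alleles(genos, pheno)
        assert out.orientation_flags[0] == "monomorphic"
        assert np.array_equal(out.dosages, genos.dosages)

    def test_exact_zero_slope_kept_and_flagged(self):
        g = np.array([0.0, 1.0, 2.0, 1.0])
        y = np.array([1.0, 2.0, 1.0, 0.0])  # cov(g, y) = 0 exactly
        assert np.dot(g - g.mean(), y - y.mean()) == 0.0
        out = cq.orient_risk_alleles(make_genos([g]), make_pheno(y))
        assert out.orientation_flags[0] == "zero_slope"
        assert np.array_equal(out.dosages[:, 0], g)


class TestFilterVariants:
    def _genos_with_hom_counts(self, counts, n=400):
        # counted allele is minor: dosage-2 count is the hom-minor count
        cols = []
        for c in counts:
            col = np.zeros(n)
            col[:c] = 2.0
            col[c : c + 50] = 1.0
            cols.append(col)
        return make_genos(cols)

    def test_boundary_fewer_than_50(self):
        genos = self._genos_with_hom_counts([49, 50])
        kept, report = cq.filter_variants(genos, min_hom=50)
        assert list(kept.variant_ids) == ["v1"]
        assert report.retained == ["v1"]
        assert report.excluded[0][0] == "v0" and report.excluded[0][2] == 49

    def test_known_counts_oracle(self):
        genos = self._genos_with_hom_counts([10, 50, 200], n=600)
        kept, report = cq.filter_variants(genos)
        assert list(kept.variant_ids) == ["v1", "v2"]
        assert [e[0] for e in report.excluded] == ["v0"]

    def test_partition_is_exact(self):
        genos = self._genos_with_hom_counts([5, 60, 49, 80])
        kept, report = cq.filter_variants(genos)
        assert sorted(report.retained + [e[0] for e in report.excluded]) == sorted(
            genos.variant_ids
        )
        assert not (set(report.retained) & {e[0] for e in report.excluded})

    def test_empty_retention_warns(self):
        genos = self._genos_with_hom_counts([3, 4])
        with pytest.warns(UserWarning):
            kept, _ = cq.filter_variants(genos)
        assert kept.n_variants == 0


class TestFitOLS:
    def test_exact_fit_no_noise(self):
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        eff = cq.fit_ols(make_pheno(2.0 * g), g)
        assert eff.beta == pytest.approx(2.0, abs=1e-12)

    def test_eight_row_normal_equations_oracle(self):
        # independent oracle: solve the normal equations directly
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
        age = np.array([45, 52, 60, 41, 66, 58, 49, 55], dtype=float)
        y = np.array([-1.2, 0.3, -2.5, 0.1, 0.8, -3.0, -0.4, 0.0])
        X = np.column_stack([np.ones(8), g, age])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hat
        sigma2 = resid @ resid / (8 - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta_hat[1] / se
        p = 2 * stats.t.sf(abs(t), df=5)
        eff = cq.fit_ols(make_pheno(y, age=age), g, covariates=["age"])
        assert eff.beta == pytest.approx(beta_hat[1], rel=1e-10)
        assert eff.se == pytest.approx(se, rel=1e-10)
        assert eff.p == pytest.approx(p, rel=1e-8)
        tcrit = stats.t.ppf(0.975, df=5)
        assert eff.ci_low == pytest.approx(beta_hat[1] - tcrit * se, rel=1e-8)

    def test_constant_dosage_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            cq.fit_ols(make_pheno(np.arange(10.0)), np.ones(10))

    def test_rank_deficiency(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, 30).astype(float)
        with pytest.raises(DegenerateDesignError):
            cq.fit_ols(make_pheno(rng.standard_normal(30), dup=g), g, covariates=["dup"])


class TestFitCQR:
    def test_location_model_flat_profile(self):
        rng = np.random.default_rng(5)
        n = 4000
        g = rng.binomial(2, 0.3, n).astype(float)
        y = -0.4 * g + rng.standard_normal(n)  # symmetric iid noise
        eff = cq.fit_cqr(make_pheno(y), g, se_method="asymptotic")
        assert np.all(np.abs(eff.betas - (-0.4)) < 4 * eff.ses)

    def test_bootstrap_reproducible_under_seed(self):
        rng = np.random.default_rng(6)
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        y = -0.3 * g + rng.standard_normal(n)
        pheno = make_pheno(y)
        grid = cq.QuantileGrid((0.25, 0.5, 0.75))
        a = cq.fit_cqr(pheno, g, grid=grid, n_boot=60, seed=42)
        b = cq.fit_cqr(pheno, g, grid=grid, n_boot=60, seed=42)
        assert np.array_equal(a.ses, b.ses)
        assert np.all(a.ses > 0)
        c = cq.fit_cqr(pheno, g, grid=grid, n_boot=60, seed=43)
        assert not np.array_equal(a.ses, c.ses)

    def test_n_boot_minimum(self):
        g = np.tile([0.0, 1.0, 2.0], 20)
        with pytest.raises(ValidationError):
            cq.fit_cqr(make_pheno(g * 2), g, n_boot=10)

    def test_check_loss_optimality(self):
        rng = np.random.default_rng(7)
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y = -0.5 * g + rng.standard_normal(n)
        pheno = make_pheno(y)
        X = np.column_stack([np.ones(n), g])
        eff = cq.fit_cqr(pheno, g, grid=cq.QuantileGrid((0.3, 0.5, 0.8)),
                         se_method="asymptotic")
        for rec in eff.records:
            base = check_loss(y, X, rec.coef, rec.q)
            scale = 1e-3 * np.maximum(np.abs(rec.coef), 1.0)
            for k in range(len(rec.coef)):
                for sign in (+1, -1):
                    pert = rec.coef.copy()
                    pert[k] += sign * scale[k]
                    assert check_loss(y, X, pert, rec.q) >= base * (1 - 1e-9)

    def test_median_matches_ols_under_symmetry(self):
        rng = np.random.default_rng(8)
        n = 20000
        g = rng.binomial(2, 0.3, n).astype(float)
        y = -0.3 * g + rng.standard_normal(n)
        pheno = make_pheno(y)
        med = cq.fit_cqr(pheno, g, grid=cq.QuantileGrid((0.5,)), se_method="asymptotic")
        ols = cq.fit_ols(pheno, g)
        combined_se = np.hypot(med.ses[0], ols.se)
        assert abs(med.betas[0] - ols.beta) < 3 * combined_se

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        y = -0.3 * g + rng.standard_normal(n)
        grid = cq.QuantileGrid((0.2, 0.5, 0.8))
        a = cq.fit_cqr(make_pheno(y), g, grid=grid, se_method="asymptotic")
        b = cq.fit_cqr(make_pheno(3.0 * y), g, grid=grid, se_method="asymptotic")
        assert np.allclose(b.betas, 3.0 * a.betas, rtol=1e-5, atol=1e-7)
        ols_a = cq.fit_ols(make_pheno(y), g)
        ols_b = cq.fit_ols(make_pheno(3.0 * y), g)
        assert ols_b.beta == pytest.approx(3.0 * ols_a.beta, rel=1e-12)

    def test_flip_antisymmetry(self):
        rng = np.random.default_rng(10)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        y = -0.3 * g + rng.standard_normal(n)
        grid = cq.QuantileGrid((0.2, 0.5, 0.8))
        a = cq.fit_cqr(make_pheno(y), g, grid=grid, se_method="asymptotic")
        b = cq.fit_cqr(make_pheno(y), 2.0 - g, grid=grid, se_method="asymptotic")
        assert np.allclose(b.betas, -a.betas, rtol=1e-5, atol=1e-7)

    def test_constant_dosage_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            cq.fit_cqr(make_pheno(np.arange(60.0)), np.full(60, 2.0))
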