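"""Shared fixtures.

The expensive null-calibration batches are session-scoped and shared between
the acceptance criteria and the calibration property tests so the suite fits
the CPU budget.
"""

import numpy as np
import pandas as pd
import pytest

import cqrmeta as cq
from cqrmeta.calibration import run_null_phenotype, run_null_snp
from cqrmeta.data import PhenotypeTable

COVARIATES = ["age", "age_squared", "sex", "array"]

# the trait carries realistic diopter-step measurement resolution: ties in
# the outcome are what drives the type-I inflation being calibrated
TRAIT_QUANTUM = 0.125


@pytest.fixture(scope="session")
def null_cohort():
    """n = 2,000 cohort with 20 implanted-null variants."""
    variants = [
        cq.VariantSpec(f"null{i:02d}", maf=0.1 + 0.3 * i / 19) for i in range(20)
    ]
    config = cq.SimulationConfig(
        n_individuals=2000,
        variants=variants,
        trait_quantum=TRAIT_QUANTUM,
        seed=20_001,
    )
    return cq.simulate_cohort(config)


@pytest.fixture(scope="session")
def null_phenotype_report(null_cohort):
    """50 permutations x 20 variants = 1,000 null tests."""
    genos, pheno = null_cohort
    return run_null_phenotype(
        genos, pheno, n_perm=50, covariates=COVARIATES, seed=555
    )


@pytest.fixture(scope="session")
def null_snp_report(null_cohort):
    """500 simulated null SNPs against the unpermuted phenotype."""
    _, pheno = null_cohort
    return run_null_snp(pheno, n_snps=500, covariates=COVARIATES, seed=556)


@pytest.fixture()
def small_cohort():
    """Cheap cohort for unit tests: 1 location-scale + 2 null variants."""
    variants = [
        cq.VariantSpec("ls1", maf=0.3, effect_model="location_scale", beta=-0.2, theta=0.2),
        cq.VariantSpec("nullA", maf=0.25),
        cq.VariantSpec("nullB", maf=0.4),
    ]
    config = cq.SimulationConfig(n_individuals=1500, variants=variants, seed=77)
    return cq.simulate_cohort(config)


@pytest.fixture()
def plain_pheno():
    """Minimal phenotype table (no covariates), continuous Gaussian trait."""
    rng = np.random.default_rng(5)
    n = 600
    return PhenotypeTable(
        pd.DataFrame(
            {
                "individual_id": [f"i{i}" for i in range(n)],
                "trait": -0.25 + 2.67 * rng.standard_normal(n),
            }
        )
    )
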