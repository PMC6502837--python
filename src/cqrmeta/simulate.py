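"""Synthetic cohort generator with analytically known quantile-effect structure.

Genotypes are Hardy-Weinberg binomial draws.  The trait is built as

    trait = mu + sum_v effect_v(g_v, E, eps) + covariate terms + noise

where a ``location`` variant contributes ``beta * g``; a ``location_scale``
variant contributes ``beta * g`` and multiplies the noise scale by
``(1 + theta * g)``, so its conditional-quantile slope at quantile q has the
closed form ``beta + sd * theta * Phi^{-1}(q)``; GxE variants contribute
``(beta + gamma * E) * g`` with E latent (standard normal, unobserved) or
observed (ordinal education score, recorded in the table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import EDU_CATEGORIES, GenotypeMatrix, PhenotypeTable
from .errors import ValidationError

EFFECT_MODELS = ("null", "location", "location_scale", "latent_gxe", "observed_gxe")

# small fixed covariate coefficients: presence matters for testing adjustment,
# realism does not
AGE_COEF = -0.005  # diopters per year, centered at 55
SEX_COEF = 0.1
ARRAY_COEF = 0.05

DEFAULT_EDU_PROBS = (0.3, 0.25, 0.25, 0.2)


@dataclass(frozen=True)
class VariantSpec:
    """Design of one simulated variant.

    beta   : trait units per risk allele (location component)
    theta  : dimensionless noise-scale coefficient (location_scale)
    gamma  : trait units per allele per exposure unit (GxE models)
    """

    variant_id: str
    maf: float
    effect_model: str = "null"
    beta: float = 0.0
    theta: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.effect_model not in EFFECT_MODELS:
            raise ValidationError(
                f"unknown effect_model {self.effect_model!r}; one of {EFFECT_MODELS}"
            )
        for name in ("beta", "theta", "gamma"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.effect_model == "null" and (self.beta or self.theta or self.gamma):
            raise ValidationError("null model requires beta = theta = gamma = 0")


@dataclass
class SimulationConfig:
    """Cohort-level generative settings; ``seed`` fully determines output."""

    n_individuals: int
    variants: Sequence[VariantSpec]
    trait_mean: float = -0.25
    trait_sd: float = 2.67
    with_age: bool = True
    with_sex: bool = True
    with_array: bool = True
    with_education: bool = False
    edu_probs: Sequence[float] = DEFAULT_EDU_PROBS
    #: measurement resolution of the trait in trait units (0 = continuous).
    #: Refraction instruments report in discrete diopter steps; rounding the
    #: trait to such a grid reproduces the tie structure of real measurements.
    trait_quantum: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if self.trait_sd <= 0:
            raise ValidationError("trait_sd must be > 0")
        probs = np.asarray(self.edu_probs, dtype=float)
        if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValidationError("edu_probs must be 4 non-negative values summing to 1")
        if self.trait_quantum < 0:
            raise ValidationError("trait_quantum must be >= 0")

    @property
    def default_covariates(self) -> list:
        cols = []
        if self.with_age:
            cols += ["age", "age_squared"]
        if self.with_sex:
            cols.append("sex")
        if self.with_array:
            cols.append("array")
        return cols


def simulate_genotypes(
    n: int, variants: Sequence[VariantSpec], seed: int
) -> GenotypeMatrix:
    """Draw HWE genotypes: dosage ~ Binomial(2, maf) per variant, independent."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if len(variants) == 0:
        raise ValidationError("at least one variant required")
    rng = np.random.default_rng(seed)
    mafs = np.array([v.maf for v in variants])
    dosages = rng.binomial(2, mafs, size=(n, len(variants))).astype(float)
    return GenotypeMatrix(
        individual_ids=np.array([f"ind_{i:06d}" for i in range(n)], dtype=object),
        variant_ids=np.array([v.variant_id for v in variants], dtype=object),
        dosages=dosages,
        effect_allele=np.array(["A"] * len(variants), dtype=object),
        other_allele=np.array(["G"] * len(variants), dtype=object),
    )


def simulate_phenotype(
    genotypes: GenotypeMatrix, config: SimulationConfig, seed: Optional[int] = None
) -> PhenotypeTable:
    """Build the trait from genotypes per the configured effect models.

    The systematic part is centered empirically so the marginal trait mean
    matches ``trait_mean``; the Gaussian noise has scale
    ``trait_sd * prod_v (1 + theta_v * g_v)`` so that location-scale variants
    carry the closed-form quantile-slope profile.
    """
    if seed is None:
        seed = config.seed
    n = genotypes.n_individuals
    if n != config.n_individuals:
        raise ValidationError(
            f"genotype rows ({n}) != config.n_individuals ({config.n_individuals})"
        )
    if genotypes.n_variants != len(config.variants):
        raise ValidationError("genotype columns do not match config.variants")
    rng = np.random.default_rng(seed)

    cols = {"individual_id": genotypes.individual_ids}
    systematic = np.zeros(n)
    if config.with_age:
        age = rng.uniform(40.0, 70.0, size=n)
        cols["age"] = age
        cols["age_squared"] = age**2
        systematic += AGE_COEF * (age - 55.0)
    if config.with_sex:
        sex = rng.integers(0, 2, size=n).astype(float)
        cols["sex"] = sex
        systematic += SEX_COEF * sex
    if config.with_array:
        array = rng.integers(0, 2, size=n).astype(float)
        cols["array"] = array
        systematic += ARRAY_COEF * array

    edu_score = None
    needs_edu = config.with_education or any(
        v.effect_model == "observed_gxe" for v in config.variants
    )
    if needs_edu:
        idx = rng.choice(4, size=n, p=np.asarray(config.edu_probs, dtype=float))
        cols["edu_category"] = np.array(EDU_CATEGORIES, dtype=object)[idx]
        edu_score = idx.astype(float)

    scale = np.ones(n)
    for j, spec in enumerate(config.variants):
        g = genotypes.dosages[:, j]
        if spec.effect_model == "null":
            continue
        if spec.effect_model == "location":
            systematic += spec.beta * g
        elif spec.effect_model == "location_scale":
            systematic += spec.beta * g
            scale *= 1.0 + spec.theta * g
        elif spec.effect_model == "latent_gxe":
            e = rng.standard_normal(n)  # unobserved exposure
            systematic += (spec.beta + spec.gamma * e) * g
        elif spec.effect_model == "observed_gxe":
            e = edu_score - float(np.mean(edu_score))
            systematic += (spec.beta + spec.gamma * e) * g
    if np.any(scale <= 0):
        raise ValidationError("theta produces non-positive noise scale for some genotype")

    noise = config.trait_sd * scale * rng.standard_normal(n)
    trait = config.trait_mean + (systematic - systematic.mean()) + noise
    if config.trait_quantum > 0:
        trait = np.round(trait / config.trait_quantum) * config.trait_quantum
    cols["trait"] = trait
    # column order: ids, trait, then covariates
    ordered = ["individual_id", "trait"] + [
        c for c in cols if c not in ("individual_id", "trait")
    ]
    return PhenotypeTable(pd.DataFrame({c: cols[c] for c in ordered}))


def simulate_cohort(config: SimulationConfig):
    """Convenience: genotypes + phenotype from one config.

    Genotype and phenotype streams use distinct child seeds spawned from
    ``config.seed`` so output is fully determined by the config.
    """
    ss = np.random.SeedSequence(config.seed)
    g_seed, p_seed = (int(s.generate_state(1)[0]) for s in ss.spawn(2))
    genos = simulate_genotypes(config.n_individuals, config.variants, seed=g_seed)
    pheno = simulate_phenotype(genos, config, seed=p_seed)
    return genos, pheno


def permute_phenotype(pheno: PhenotypeTable, seed: int) -> PhenotypeTable:
    """Uniform random permutation of trait values across individuals.

    Covariates stay attached to their original individuals; the multiset of
    trait values is preserved exactly.
    """
    if pheno.n == 0:
        raise ValidationError("cannot permute an empty phenotype table")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pheno.n)
    return pheno.with_trait(pheno.trait[perm])


def compute_avmse(sphere_right, cyl_right, sphere_left, cyl_left):
    """Mean spherical equivalent: sphere + cylinder/2, averaged between eyes.

    Accepts scalars or arrays.  If one eye is entirely missing (NaN) the
    available eye is used; if both are missing the result is NaN, marking the
    individual for exclusion.
    """
    sr = np.asarray(sphere_right, dtype=float)
    cr = np.asarray(cyl_right, dtype=float)
    sl = np.asarray(sphere_left, dtype=float)
    cl = np.asarray(cyl_left, dtype=float)
    right = sr + cr / 2.0
    left = sl + cl / 2.0
    stacked = np.stack([right, left])
    both_missing = np.isnan(right) & np.isnan(left)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        out = np.where(both_missing, np.nan, np.nanmean(stacked, axis=0))
    if out.ndim == 0:
        return float(out)
    return out


def quantile_slope_oracle(q, beta: float, sd: float, theta: float):
    """Closed-form conditional-quantile slope for a location-scale variant."""
    from scipy.stats import norm

    return beta + sd * theta * norm.ppf(np.asarray(q, dtype=float))
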