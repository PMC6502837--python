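"""Empirical calibration of the two-stage quantile-profile test.

Null batches (permuted phenotype, or freshly simulated null SNPs) give the
per-coefficient null distribution of the meta-regression z statistics; the
inflation factor lambda = median(z^2) / 0.4549 rescales tests and CIs
(genomic control).  Power is measured by subsampling and re-testing at a
ladder of sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .data import GenotypeMatrix, PhenotypeTable, align
from .errors import DegenerateInputError, ValidationError
from .meta import MetaRegResult, Z975, fit_meta_regression
from .regression import DEFAULT_GRID, QuantileGrid, fit_cqr
from .simulate import permute_phenotype

#: median of the chi-square(1) distribution, fixed at 4 d.p. for reproducibility
CHI2_1_MEDIAN = 0.4549

COEF_NAMES = ("beta0", "beta1", "beta2")


def cqr_mr_single(
    pheno: PhenotypeTable,
    dosage: np.ndarray,
    covariates: Sequence[str],
    grid: QuantileGrid,
    seed: int = 0,
    se_method: str = "asymptotic",
    n_boot: int = 200,
    variant_id: str = "",
) -> MetaRegResult:
    """One full CQR + meta-regression pass for a single variant."""
    eff = fit_cqr(
        pheno,
        dosage,
        covariates=covariates,
        grid=grid,
        n_boot=n_boot,
        seed=seed,
        se_method=se_method,
        variant_id=variant_id,
    )
    return fit_meta_regression(eff)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class CalibrationReport:
    """Null-batch z and p statistics for the three profile coefficients."""

    design: str  # 'null_phenotype' | 'null_snp'
    z: np.ndarray  # (n_tests, 3)
    p: np.ndarray  # (n_tests, 3)
    seed: int
    grid: Tuple[float, ...]
    maf: Optional[np.ndarray] = None  # per-test MAF (null_snp design)

    @property
    def n_tests(self) -> int:
        return self.z.shape[0]

    def lambdas(self) -> np.ndarray:
        return np.array([estimate_inflation(self.z[:, j]) for j in range(3)])

    def error_rate(self, alpha: float = 0.05, lambdas=None) -> np.ndarray:
        """Per-coefficient empirical type-I error; if ``lambdas`` given, the
        rate is recomputed from genomic-control-rescaled statistics."""
        if lambdas is None:
            return np.mean(self.p < alpha, axis=0)
        lam = np.asarray(lambdas, dtype=float)
        p_corr = 2.0 * stats.norm.sf(np.abs(self.z) / np.sqrt(lam))
        return np.mean(p_corr < alpha, axis=0)

    def error_rate_ci(self, alpha: float = 0.05, level: float = 0.95):
        """Clopper-Pearson Monte-Carlo CI on each uncorrected error rate."""
        k = np.sum(self.p < alpha, axis=0)
        lo, hi = [], []
        for kk in k:
            ci = stats.binomtest(int(kk), self.n_tests).proportion_ci(
                confidence_level=level, method="exact"
            )
            lo.append(ci.low)
            hi.append(ci.high)
        return np.array(lo), np.array(hi)

    def lambda_by_maf_bin(self, n_bins: int = 4) -> Dict[str, np.ndarray]:
        if self.maf is None:
            raise ValidationError("per-test MAF only recorded for the null_snp design")
        edges = np.quantile(self.maf, np.linspace(0, 1, n_bins + 1))
        edges[-1] += 1e-12
        out = {"edges": edges, "lambda": np.zeros((n_bins, 3)), "n": np.zeros(n_bins, int)}
        for b in range(n_bins):
            sel = (self.maf >= edges[b]) & (self.maf < edges[b + 1])
            out["n"][b] = int(sel.sum())
            for j in range(3):
                out["lambda"][b, j] = estimate_inflation(self.z[sel, j])
        return out

    def to_dict(self, alpha: float = 0.05) -> dict:
        lam = self.lambdas()
        raw = self.error_rate(alpha)
        corr = self.error_rate(alpha, lambdas=lam)
        lo, hi = self.error_rate_ci(alpha)
        return {
            "design": self.design,
            "n_tests": self.n_tests,
            "alpha": alpha,
            "seed": self.seed,
            "grid": list(self.grid),
            "coefficients": {
                name: {
                    "lambda": float(lam[j]),
                    "type1_error": float(raw[j]),
                    "type1_error_ci95": [float(lo[j]), float(hi[j])],
                    "type1_error_corrected": float(corr[j]),
                }
                for j, name in enumerate(COEF_NAMES)
            },
        }


@dataclass
class PowerCurve:
    sample_sizes: List[int]
    n_reps: int
    alpha: float
    #: rejection proportion per size for the combined min(p1, p2) rule
    power: np.ndarray
    #: per-coefficient rejection proportions, shape (n_sizes, 3)
    power_by_coef: np.ndarray
    n_tests: int = 0

    def to_dict(self) -> dict:
        return {
            "sample_sizes": list(map(int, self.sample_sizes)),
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "power": [float(v) for v in self.power],
            "power_by_coef": {
                name: [float(v) for v in self.power_by_coef[:, j]]
                for j, name in enumerate(COEF_NAMES)
            },
        }


# ---------------------------------------------------------------------------
# bookkeeping (protocol arithmetic)
# ---------------------------------------------------------------------------


def null_phenotype_test_count(n_perm: int, n_variants: int) -> int:
    """Tests accumulated per coefficient: permutations x variants."""
    if n_perm < 1 or n_variants < 1:
        raise ValidationError("n_perm and n_variants must be >= 1")
    return n_perm * n_variants


def power_test_count(n_variants: int, sample_sizes: Sequence[int], n_reps: int) -> int:
    """Tests used by the power protocol: variants x sizes x repeats."""
    if n_variants < 1 or n_reps < 1 or len(sample_sizes) < 1:
        raise ValidationError("need >= 1 variant, size, and repeat")
    return n_variants * len(sample_sizes) * n_reps


# ---------------------------------------------------------------------------
# null designs
# ---------------------------------------------------------------------------


def run_null_phenotype(
    genos: GenotypeMatrix,
    pheno: PhenotypeTable,
    n_perm: int,
    grid: QuantileGrid = DEFAULT_GRID,
    covariates: Sequence[str] = (),
    seed: int = 0,
    se_method: str = "asymptotic",
    n_boot: int = 200,
) -> CalibrationReport:
    """Permute the trait ``n_perm`` times; test every variant per permutation."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    genos, pheno = align(genos, pheno)
    ss = np.random.SeedSequence(seed)
    perm_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_perm)]
    zs, ps = [], []
    for perm_seed in perm_seeds:
        null_pheno = permute_phenotype(pheno, perm_seed)
        for j in range(genos.n_variants):
            res = cqr_mr_single(
                null_pheno,
                genos.dosages[:, j],
                covariates,
                grid,
                seed=perm_seed + j,
                se_method=se_method,
                n_boot=n_boot,
            )
            zs.append(res.z)
            ps.append(res.p)
    return CalibrationReport(
        design="null_phenotype",
        z=np.asarray(zs),
        p=np.asarray(ps),
        seed=seed,
        grid=grid.quantiles,
    )


def run_null_snp(
    pheno: PhenotypeTable,
    n_snps: int,
    maf_range: Tuple[float, float] = (0.05, 0.45),
    grid: QuantileGrid = DEFAULT_GRID,
    covariates: Sequence[str] = (),
    seed: int = 0,
    se_method: str = "asymptotic",
    n_boot: int = 200,
) -> CalibrationReport:
    """Test the observed trait against freshly simulated independent SNPs."""
    if n_snps < 1:
        raise ValidationError("n_snps must be >= 1")
    lo, hi = maf_range
    if not (0 < lo < hi <= 0.5):
        raise ValidationError(f"degenerate MAF range {maf_range}")
    if np.var(pheno.trait) == 0:
        raise DegenerateInputError("phenotype is constant; quantile fits undefined")
    rng = np.random.default_rng(seed)
    zs, ps, mafs = [], [], []
    for s in range(n_snps):
        maf = rng.uniform(lo, hi)
        g = rng.binomial(2, maf, size=pheno.n).astype(float)
        if np.var(g) == 0:
            continue  # monomorphic draw at tiny n; skip
        res = cqr_mr_single(
            pheno, g, covariates, grid, seed=seed + s, se_method=se_method, n_boot=n_boot
        )
        zs.append(res.z)
        ps.append(res.p)
        mafs.append(maf)
    if not zs:
        raise DegenerateInputError("no polymorphic null SNPs could be simulated")
    return CalibrationReport(
        design="null_snp",
        z=np.asarray(zs),
        p=np.asarray(ps),
        seed=seed,
        grid=grid.quantiles,
        maf=np.asarray(mafs),
    )


# ---------------------------------------------------------------------------
# genomic control
# ---------------------------------------------------------------------------


def estimate_inflation(null_z: np.ndarray) -> float:
    """lambda = median(z^2) / median(chi-square_1); no clamping at 1."""
    z = np.asarray(null_z, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < 30:
        raise ValidationError(f"need >= 30 null statistics, got {len(z)}")
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def apply_genomic_control(
    res: MetaRegResult, lambdas: Sequence[float]
) -> MetaRegResult:
    """Rescale z by 1/sqrt(lambda), SE by sqrt(lambda); rebuild CIs and p.

    Point estimates are unchanged; the result is flagged ``corrected``.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.shape == ():
        lam = np.repeat(lam, 3)
    if lam.shape != (3,):
        raise ValidationError("lambdas must be a scalar or length-3 sequence")
    if np.any(lam <= 0):
        raise ValidationError("lambdas must be > 0")
    root = np.sqrt(lam)
    se = res.se * root
    z = res.z / root
    p = 2.0 * stats.norm.sf(np.abs(z))
    return replace(
        res,
        se=se,
        z=z,
        p=p,
        ci_low=res.beta - Z975 * se,
        ci_high=res.beta + Z975 * se,
        cov=res.cov * np.outer(root, root),
        corrected=True,
    )


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def evaluate_power(
    genos: GenotypeMatrix,
    pheno: PhenotypeTable,
    sample_sizes: Sequence[int],
    n_reps: int,
    alpha: float = 0.05,
    grid: QuantileGrid = DEFAULT_GRID,
    covariates: Sequence[str] = (),
    lambdas: Optional[Sequence[float]] = None,
    seed: int = 0,
    se_method: str = "asymptotic",
    n_boot: int = 200,
) -> PowerCurve:
    """Rejection proportion at each sample size; rejection means corrected
    min(p1, p2) < alpha.

    Subsamples are nested within a repeat (a single permutation truncated to
    each size) and derived only from ``seed`` and the repeat index, so runs
    with different grids but equal seeds are paired.
    """
    genos, pheno = align(genos, pheno)
    n = pheno.n
    sizes = [int(s) for s in sample_sizes]
    if any(s > n for s in sizes):
        raise ValidationError(f"sample size exceeds cohort n = {n}")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    lam = np.ones(3) if lambdas is None else np.asarray(lambdas, dtype=float)

    reject = np.zeros((len(sizes), 3))
    reject_any = np.zeros(len(sizes))
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_reps)]
    for rep, rep_seed in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_seed)
        order = rng.permutation(n)
        for si, size in enumerate(sizes):
            idx = order[:size]
            sub_pheno = pheno.subset(idx)
            for j in range(genos.n_variants):
                res = cqr_mr_single(
                    sub_pheno,
                    genos.dosages[idx, j],
                    covariates,
                    grid,
                    seed=rep_seed + j,
                    se_method=se_method,
                    n_boot=n_boot,
                )
                res = apply_genomic_control(res, lam)
                reject[si] += res.p < alpha
                reject_any[si] += min(res.p[1], res.p[2]) < alpha
    denom = n_reps * genos.n_variants
    return PowerCurve(
        sample_sizes=sizes,
        n_reps=n_reps,
        alpha=alpha,
        power=reject_any / denom,
        power_by_coef=reject / denom,
        n_tests=power_test_count(genos.n_variants, sizes, n_reps),
    )


def compare_quantile_grids(
    genos: GenotypeMatrix,
    pheno: PhenotypeTable,
    grids: Optional[Dict[str, QuantileGrid]] = None,
    n_perm: int = 20,
    sample_sizes: Sequence[int] = (2000,),
    n_reps: int = 10,
    alpha: float = 0.05,
    covariates: Sequence[str] = (),
    seed: int = 0,
    se_method: str = "asymptotic",
) -> List[dict]:
    """Run the null-phenotype and power protocols once per grid on shared
    seeds (paired comparison); returns one summary row per grid."""
    if grids is None:
        grids = {str(k): QuantileGrid.named(k) for k in (5, 9, 10, 19)}
    rows = []
    for name, grid in grids.items():
        null_rep = run_null_phenotype(
            genos, pheno, n_perm, grid=grid, covariates=covariates, seed=seed,
            se_method=se_method,
        )
        lam = null_rep.lambdas()
        curve = evaluate_power(
            genos, pheno, sample_sizes, n_reps, alpha=alpha, grid=grid,
            covariates=covariates, lambdas=lam, seed=seed, se_method=se_method,
        )
        row = {
            "grid": name,
            "n_quantiles": len(grid),
            "lambda": [float(v) for v in lam],
            "type1_error": [float(v) for v in null_rep.error_rate(alpha)],
            "type1_error_corrected": [
                float(v) for v in null_rep.error_rate(alpha, lambdas=lam)
            ],
            "power": [float(v) for v in curve.power],
            "sample_sizes": list(map(int, sample_sizes)),
        }
        rows.append(row)
    return rows
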