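"""Per-variant effect estimation: OLS and conditional quantile regression.

OLS gives the conventional constant-effect estimate.  CQR minimizes the
check loss at each quantile of a grid, with either a seeded nonparametric
(x, y)-pair bootstrap or asymptotic (kernel sandwich) standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .data import GenotypeMatrix, PhenotypeTable, align
from .errors import DegenerateDesignError, ValidationError

DEFAULT_COVARIATES = ("age", "age_squared", "sex", "array")


@dataclass(frozen=True)
class QuantileGrid:
    """Strictly increasing quantiles in the open unit interval."""

    quantiles: Tuple[float, ...]

    def __post_init__(self):
        q = np.asarray(self.quantiles, dtype=float)
        if q.ndim != 1 or len(q) == 0:
            raise ValidationError("quantile grid must be a non-empty 1-d sequence")
        if not np.all((q > 0) & (q < 1)):
            raise ValidationError("quantiles must lie strictly inside (0, 1)")
        if not np.all(np.diff(q) > 0):
            raise ValidationError("quantiles must be strictly increasing")
        object.__setattr__(self, "quantiles", tuple(float(v) for v in q))

    def __len__(self) -> int:
        return len(self.quantiles)

    def __iter__(self):
        return iter(self.quantiles)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.quantiles)

    # canonical grids: 9-point is the default protocol; 19/10/5 are the
    # alternatives explored when choosing a grid
    @classmethod
    def nine(cls) -> "QuantileGrid":
        return cls(tuple(np.round(np.arange(0.1, 0.95, 0.1), 10)))

    @classmethod
    def nineteen(cls) -> "QuantileGrid":
        return cls(tuple(np.round(np.arange(0.05, 0.975, 0.05), 10)))

    @classmethod
    def ten(cls) -> "QuantileGrid":
        return cls(tuple(np.round(np.arange(0.05, 0.975, 0.1), 10)))

    @classmethod
    def five(cls) -> "QuantileGrid":
        return cls(tuple(np.round(np.arange(0.1, 0.95, 0.2), 10)))

    @classmethod
    def named(cls, n: int) -> "QuantileGrid":
        try:
            return {5: cls.five, 9: cls.nine, 10: cls.ten, 19: cls.nineteen}[n]()
        except KeyError:
            raise ValidationError(f"no named {n}-point grid (choose 5, 9, 10, 19)")


DEFAULT_GRID = QuantileGrid.nine()


@dataclass
class OLSEffect:
    variant_id: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass
class QuantileEffect:
    """CQR estimate at one quantile; ``ok`` False marks a per-quantile failure."""

    q: float
    beta: float
    se: float
    n_boot: int
    ok: bool = True
    coef: Optional[np.ndarray] = None  # full coefficient vector, for diagnostics


@dataclass
class QuantileEffectSet:
    variant_id: str
    records: List[QuantileEffect]

    @property
    def quantiles(self) -> np.ndarray:
        return np.array([r.q for r in self.records])

    @property
    def betas(self) -> np.ndarray:
        return np.array([r.beta for r in self.records])

    @property
    def ses(self) -> np.ndarray:
        return np.array([r.se for r in self.records])

    @property
    def ok(self) -> np.ndarray:
        return np.array([r.ok for r in self.records])


@dataclass
class FilterReport:
    retained: List[str]
    excluded: List[Tuple[str, str, int]]  # (variant_id, reason, hom_minor_count)


# ---------------------------------------------------------------------------
# orientation and filtering
# ---------------------------------------------------------------------------


def orient_risk_alleles(
    genos: GenotypeMatrix, pheno: PhenotypeTable
) -> GenotypeMatrix:
    """Orient each variant so the counted allele associates with a more
    negative trait value (marginal OLS slope <= 0).

    Flipping stores ``g -> 2 - g`` and swaps the allele labels; monomorphic
    variants and exact-zero slopes keep the input orientation and are flagged.
    """
    genos, pheno = align(genos, pheno)
    y = pheno.trait
    y_c = y - y.mean()
    dosages = genos.dosages.copy()
    effect = genos.effect_allele.copy()
    other = genos.other_allele.copy()
    flipped = genos.flipped.copy()
    flags = genos.orientation_flags.copy()
    for j in range(genos.n_variants):
        g = dosages[:, j]
        mask = ~np.isnan(g)
        var_g = np.var(g[mask]) if mask.any() else 0.0
        if var_g == 0.0:
            flags[j] = "monomorphic"
            continue
        slope = np.dot(g[mask] - g[mask].mean(), y_c[mask]) / (var_g * mask.sum())
        if slope > 0:
            dosages[:, j] = 2.0 - g
            effect[j], other[j] = other[j], effect[j]
            flipped[j] = ~flipped[j]
        elif slope == 0.0:
            flags[j] = "zero_slope"
    out = GenotypeMatrix(
        individual_ids=genos.individual_ids,
        variant_ids=genos.variant_ids,
        dosages=dosages,
        effect_allele=effect,
        other_allele=other,
        chrom=genos.chrom,
        pos=genos.pos,
        flipped=flipped,
        orientation_flags=flags,
        missing_rate=genos.missing_rate,
    )
    return out


def filter_variants(
    genos: GenotypeMatrix, min_hom: int = 50
) -> Tuple[GenotypeMatrix, FilterReport]:
    """Drop variants with fewer than ``min_hom`` minor-allele homozygotes."""
    counts = genos.hom_minor_count
    keep, retained, excluded = [], [], []
    for j, vid in enumerate(genos.variant_ids):
        if counts[j] < min_hom:
            excluded.append((str(vid), f"hom_minor_count {counts[j]} < {min_hom}", int(counts[j])))
        else:
            keep.append(j)
            retained.append(str(vid))
    if not keep:
        warnings.warn("all variants excluded by the homozygote filter")
    report = FilterReport(retained=retained, excluded=excluded)
    return genos.subset_variants(keep), report


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def _design(
    pheno: PhenotypeTable, dosage: np.ndarray, covariates: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    dosage = np.asarray(dosage, dtype=float)
    if dosage.shape != (pheno.n,):
        raise ValidationError(
            f"dosage length {dosage.shape} does not match phenotype rows {pheno.n}"
        )
    if np.isnan(dosage).any():
        raise ValidationError("dosage contains NaN; impute before fitting")
    if np.var(dosage) == 0:
        raise DegenerateDesignError("constant dosage column")
    C = pheno.covariate_matrix(covariates)
    X = np.column_stack([np.ones(pheno.n), dosage, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient")
    return pheno.trait, X


def fit_ols(
    pheno: PhenotypeTable,
    dosage: np.ndarray,
    covariates: Sequence[str] = (),
    variant_id: str = "",
) -> OLSEffect:
    """Least squares of trait on dosage + covariates; genotype coefficient
    reported with t-based two-sided p and 95% CI."""
    y, X = _design(pheno, dosage, covariates)
    if len(y) < X.shape[1] + 1:
        raise ValidationError("too few rows for the requested design")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return OLSEffect(
        variant_id=variant_id,
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p=float(res.pvalues[1]),
        n=len(y),
    )


def _quantreg_beta(y, X, q, max_iter=250):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IterationLimitWarning)
        res = sm.QuantReg(y, X).fit(q=q, max_iter=max_iter)
    return res


def fit_cqr(
    pheno: PhenotypeTable,
    dosage: np.ndarray,
    covariates: Sequence[str] = (),
    grid: QuantileGrid = DEFAULT_GRID,
    n_boot: int = 200,
    seed: int = 0,
    se_method: str = "bootstrap",
    variant_id: str = "",
) -> QuantileEffectSet:
    """Check-loss regression of trait on dosage + covariates at each grid
    quantile.

    ``se_method='bootstrap'`` resamples (x, y) pairs ``n_boot`` times under
    ``seed`` (same resamples across quantiles); ``'asymptotic'`` uses the
    kernel-sandwich standard error, which is far cheaper and is the default
    inside the large calibration loops.
    """
    if se_method not in ("bootstrap", "asymptotic"):
        raise ValidationError(f"unknown se_method {se_method!r}")
    if se_method == "bootstrap" and n_boot < 50:
        raise ValidationError("n_boot must be >= 50 for bootstrap standard errors")
    y, X = _design(pheno, dosage, covariates)
    n = len(y)

    records: List[QuantileEffect] = []
    point = {}
    for q in grid:
        try:
            res = _quantreg_beta(y, X, q)
            point[q] = (float(res.params[1]), np.asarray(res.params), float(res.bse[1]))
        except Exception:
            point[q] = None

    if se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boot = {q: [] for q in grid if point[q] is not None}
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            yb, Xb = y[idx], X[idx]
            for q in boot:
                try:
                    boot[q].append(float(_quantreg_beta(yb, Xb, q).params[1]))
                except Exception:
                    pass

    for q in grid:
        if point[q] is None:
            records.append(QuantileEffect(q=q, beta=np.nan, se=np.nan, n_boot=0, ok=False))
            continue
        beta, coef, se_asym = point[q]
        if se_method == "bootstrap":
            draws = np.asarray(boot[q])
            if len(draws) < max(30, n_boot // 2):
                records.append(
                    QuantileEffect(q=q, beta=beta, se=np.nan, n_boot=len(draws), ok=False, coef=coef)
                )
                continue
            se = float(np.std(draws, ddof=1))
            nb = len(draws)
        else:
            se, nb = se_asym, 0
        ok = np.isfinite(se) and se > 0
        records.append(QuantileEffect(q=q, beta=beta, se=se, n_boot=nb, ok=ok, coef=coef))
    return QuantileEffectSet(variant_id=variant_id, records=records)


def check_loss(y: np.ndarray, X: np.ndarray, coef: np.ndarray, q: float) -> float:
    """Asymmetric absolute deviation objective evaluated at ``coef``."""
    r = y - X @ coef
    return float(np.sum(r * (q - (r < 0))))
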