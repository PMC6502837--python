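"""Unweighted polygenic score and education-stratified quantile profiles.

The score is a plain risk-allele count over oriented variants, standardized
on the full sample so per-SD effects are comparable across education strata.
Stratified CQR fits the trait on the standardized score within each
education category; profiles are contrasted across strata with
independent-samples normal tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import EDU_CATEGORIES, GenotypeMatrix, PhenotypeTable
from .errors import DegenerateInputError, ValidationError
from .meta import MetaRegResult, fit_meta_regression
from .regression import DEFAULT_GRID, QuantileGrid, fit_cqr

#: minimum individuals per stratum so extreme-quantile fits have support
MIN_STRATUM_SIZE = 500


@dataclass
class PRSVector:
    individual_id: np.ndarray
    raw_score: np.ndarray  # integer allele count
    z_score: np.ndarray  # standardized on the full sample

    @property
    def n(self) -> int:
        return len(self.raw_score)


@dataclass
class StratifiedProfile:
    stratum: str
    n: int
    quantiles: np.ndarray
    beta: np.ndarray  # trait units per +1 PRS SD
    se: np.ndarray

    def ci(self, level: float = 0.95):
        zc = stats.norm.ppf(0.5 + level / 2)
        return self.beta - zc * self.se, self.beta + zc * self.se


@dataclass
class StratifiedResult:
    profiles: List[StratifiedProfile]
    meta: Dict[str, MetaRegResult]
    contrasts: pd.DataFrame  # stratum_a, stratum_b, q, diff, se, z, p
    skipped: List[str]


def build_prs(genos: GenotypeMatrix) -> PRSVector:
    """Sum of risk-allele dosages, standardized by full-sample mean/SD.

    Orientation must already be applied: every column counts the
    trait-lowering allele.
    """
    if genos.n_variants == 0:
        raise ValidationError("cannot build a score from zero variants")
    if np.isnan(genos.dosages).any():
        raise ValidationError("dosages contain NaN; impute before scoring")
    raw = genos.dosages.sum(axis=1)
    sd = raw.std()
    if sd == 0:
        raise DegenerateInputError("polygenic score is constant; cannot standardize")
    return PRSVector(
        individual_id=genos.individual_ids,
        raw_score=raw,
        z_score=(raw - raw.mean()) / sd,
    )


def assign_edu_category(
    age_completed: Optional[float] = None, degree: Optional[bool] = None
) -> str:
    """Map age-completed-education (or a degree flag) to a category label.

    Degree holders are assigned age 21 (hence '21-26').  Out-of-range ages
    clamp to the nearest category with a warning.
    """
    if degree:
        age_completed = 21.0
    if age_completed is None:
        raise ValidationError("need age_completed or degree flag")
    age = float(age_completed)
    if age < 13:
        warnings.warn(f"age_completed {age} below 13; clamped to category 13-15")
        return "13-15"
    if age > 26:
        warnings.warn(f"age_completed {age} above 26; clamped to category 21-26")
        return "21-26"
    if age <= 15:
        return "13-15"
    if age < 17:
        return "16"
    if age <= 20:
        return "17-20"
    return "21-26"


def assign_edu_categories(
    age_completed: Sequence[float], degree: Optional[Sequence[bool]] = None
) -> np.ndarray:
    """Vectorized :func:`assign_edu_category`."""
    age = np.asarray(age_completed, dtype=float)
    if degree is None:
        degree = np.zeros(len(age), dtype=bool)
    return np.array(
        [
            assign_edu_category(a if not d else None, degree=bool(d))
            for a, d in zip(age, degree)
        ],
        dtype=object,
    )


def stratified_cqr_mr(
    pheno: PhenotypeTable,
    prs: PRSVector,
    grid: QuantileGrid = DEFAULT_GRID,
    covariates: Sequence[str] = (),
    seed: int = 0,
    se_method: str = "asymptotic",
    n_boot: int = 200,
    min_stratum_size: int = MIN_STRATUM_SIZE,
) -> StratifiedResult:
    """Per-education-stratum CQR of trait on the standardized score.

    Each stratum gets a quantile profile and a meta-regression fit; strata
    below ``min_stratum_size`` are skipped with a warning.  Cross-stratum
    contrasts of beta_q use independent normal differences (strata are
    disjoint individuals); multiplicity across quantiles is reported, not
    corrected.
    """
    if "edu_category" not in pheno.df.columns:
        raise ValidationError("phenotype table has no edu_category column")
    if prs.n != pheno.n or not np.array_equal(prs.individual_id, pheno.individual_ids):
        raise ValidationError("PRS vector and phenotype table are not aligned")

    profiles: List[StratifiedProfile] = []
    meta: Dict[str, MetaRegResult] = {}
    skipped: List[str] = []
    labels = pheno.df["edu_category"].to_numpy(dtype=object)
    for si, stratum in enumerate(EDU_CATEGORIES):
        idx = np.flatnonzero(labels == stratum)
        if len(idx) == 0:
            continue
        if len(idx) < min_stratum_size:
            warnings.warn(
                f"stratum {stratum} has {len(idx)} < {min_stratum_size} individuals; skipped"
            )
            skipped.append(stratum)
            continue
        sub = pheno.subset(idx)
        eff = fit_cqr(
            sub,
            prs.z_score[idx],
            covariates=covariates,
            grid=grid,
            n_boot=n_boot,
            seed=seed + si,
            se_method=se_method,
            variant_id=f"PRS[{stratum}]",
        )
        profiles.append(
            StratifiedProfile(
                stratum=stratum,
                n=len(idx),
                quantiles=eff.quantiles,
                beta=eff.betas,
                se=eff.ses,
            )
        )
        meta[stratum] = fit_meta_regression(eff)

    rows = []
    for a in range(len(profiles)):
        for b in range(a + 1, len(profiles)):
            pa, pb = profiles[a], profiles[b]
            for k, q in enumerate(pa.quantiles):
                diff = pa.beta[k] - pb.beta[k]
                se = float(np.hypot(pa.se[k], pb.se[k]))
                z = diff / se if se > 0 else np.nan
                rows.append(
                    {
                        "stratum_a": pa.stratum,
                        "stratum_b": pb.stratum,
                        "q": q,
                        "diff": diff,
                        "se": se,
                        "z": z,
                        "p": 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    }
                )
    contrasts = pd.DataFrame(
        rows, columns=["stratum_a", "stratum_b", "q", "diff", "se", "z", "p"]
    )
    return StratifiedResult(
        profiles=profiles, meta=meta, contrasts=contrasts, skipped=skipped
    )
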