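"""Core data containers: genotype matrix and phenotype table.

Genotypes are stored as additive dosages of the *counted* (effect) allele,
one column per variant.  Dosages are floats in [0, 2]; hard-call-dependent
quantities (homozygote counts) round to the nearest integer.  The phenotype
table wraps a pandas DataFrame with a validated column contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

EDU_CATEGORIES = ("13-15", "16", "17-20", "21-26")

#: ordinal score used when an education category enters a model numerically
EDU_SCORES = {c: float(i) for i, c in enumerate(EDU_CATEGORIES)}

REQUIRED_PHENO_COLUMNS = ("individual_id", "trait")


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosage matrix with variant metadata.

    Parameters
    ----------
    individual_ids : sequence of str
    variant_ids : sequence of str
    dosages : ndarray, shape (n_individuals, n_variants)
        Counted-allele dosage per individual per variant, in [0, 2].
        NaN marks missing calls (impute before regression).
    effect_allele, other_allele : sequences of str
        Per-variant allele labels; ``effect_allele`` is the counted allele.
    chrom, pos : optional per-variant coordinates (pos is 1-based).
    flipped : bool array marking variants whose orientation was reversed.
    orientation_flags : per-variant string flag ('' when unremarkable).
    """

    individual_ids: np.ndarray
    variant_ids: np.ndarray
    dosages: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    chrom: Optional[np.ndarray] = None
    pos: Optional[np.ndarray] = None
    flipped: Optional[np.ndarray] = None
    orientation_flags: Optional[np.ndarray] = None
    missing_rate: Optional[np.ndarray] = None

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValidationError(
                f"{len(self.individual_ids)} individual ids for {n} dosage rows"
            )
        if len(self.variant_ids) != m:
            raise ValidationError(
                f"{len(self.variant_ids)} variant ids for {m} dosage columns"
            )
        if len(self.effect_allele) != m or len(self.other_allele) != m:
            raise ValidationError("allele label arrays must match variant count")
        same = [
            str(a) == str(b)
            for a, b in zip(self.effect_allele, self.other_allele)
        ]
        if any(same):
            bad = self.variant_ids[np.asarray(same)]
            raise ValidationError(f"effect and other allele identical for {list(bad)}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValidationError("dosages must lie in [0, 2]")
        if self.flipped is None:
            self.flipped = np.zeros(m, dtype=bool)
        if self.orientation_flags is None:
            self.orientation_flags = np.array([""] * m, dtype=object)

    # -- derived quantities -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def effect_allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele (mean dosage / 2)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.effect_allele_freq
        return np.minimum(p, 1.0 - p)

    @property
    def hom_minor_count(self) -> np.ndarray:
        """Number of individuals homozygous for the minor allele (hard calls)."""
        hard = np.round(self.dosages)
        p = self.effect_allele_freq
        counts = np.empty(self.n_variants, dtype=int)
        for j in range(self.n_variants):
            col = hard[:, j]
            col = col[~np.isnan(col)]
            # minor allele is the counted allele iff its frequency <= 0.5
            hom_value = 2.0 if p[j] <= 0.5 else 0.0
            counts[j] = int(np.sum(col == hom_value))
        return counts

    # -- manipulation -------------------------------------------------------

    def variant_index(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variant_ids == variant_id)
        if idx.size == 0:
            raise KeyError(variant_id)
        return int(idx[0])

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)]

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return replace(
            self,
            variant_ids=self.variant_ids[keep],
            dosages=self.dosages[:, keep],
            effect_allele=self.effect_allele[keep],
            other_allele=self.other_allele[keep],
            chrom=None if self.chrom is None else np.asarray(self.chrom)[keep],
            pos=None if self.pos is None else np.asarray(self.pos)[keep],
            flipped=self.flipped[keep],
            orientation_flags=self.orientation_flags[keep],
            missing_rate=None if self.missing_rate is None else self.missing_rate[keep],
        )

    def subset_individuals(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return replace(
            self,
            individual_ids=self.individual_ids[keep],
            dosages=self.dosages[keep, :],
        )


class PhenotypeTable:
    """Per-individual trait (diopters) plus covariates and optional strata.

    Wraps a DataFrame with required columns ``individual_id`` and ``trait``;
    typical covariates are ``age``, ``age_squared``, ``sex``, ``array`` and
    optional principal components / ``edu_category``.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        for col in REQUIRED_PHENO_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"phenotype table missing required column {col!r}")
        if df["individual_id"].duplicated().any():
            dups = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
            raise ValidationError(f"duplicated individual_id values: {dups[:5]}")
        if df["trait"].isna().any():
            raise ValidationError("phenotype table contains missing trait values")
        if "edu_category" in df.columns:
            present = df["edu_category"].dropna()
            bad = set(present.unique()) - set(EDU_CATEGORIES)
            if bad:
                raise ValidationError(f"unknown edu_category labels: {sorted(bad)}")
        if "age" in df.columns and "age_squared" not in df.columns:
            df = df.assign(age_squared=df["age"] ** 2)
        self.df = df

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def trait(self) -> np.ndarray:
        return self.df["trait"].to_numpy(dtype=float)

    @property
    def individual_ids(self) -> np.ndarray:
        return self.df["individual_id"].to_numpy(dtype=object)

    def covariate_matrix(self, covariates: Sequence[str]) -> np.ndarray:
        missing = [c for c in covariates if c not in self.df.columns]
        if missing:
            raise ValidationError(f"covariate columns not present: {missing}")
        if not covariates:
            return np.empty((self.n, 0))
        return self.df[list(covariates)].to_numpy(dtype=float)

    def with_trait(self, values: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(self.df.assign(trait=np.asarray(values, dtype=float)))

    def subset(self, keep: Sequence[int]) -> "PhenotypeTable":
        return PhenotypeTable(self.df.iloc[np.asarray(keep, dtype=int)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhenotypeTable(n={self.n}, columns={list(self.df.columns)})"


def align(genos: GenotypeMatrix, pheno: PhenotypeTable):
    """Intersect genotype and phenotype individuals, preserving genotype order.

    Returns aligned (GenotypeMatrix, PhenotypeTable); raises if the
    intersection is empty.
    """
    pheno_index = {iid: i for i, iid in enumerate(pheno.individual_ids)}
    g_keep, p_keep = [], []
    for i, iid in enumerate(genos.individual_ids):
        j = pheno_index.get(iid)
        if j is not None:
            g_keep.append(i)
            p_keep.append(j)
    if not g_keep:
        raise ValidationError("no individuals shared between genotypes and phenotypes")
    if len(g_keep) == genos.n_individuals and g_keep == p_keep == list(range(pheno.n)):
        return genos, pheno
    return genos.subset_individuals(g_keep), pheno.subset(p_keep)
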