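"""Readers/writers for VCF, dosage TSV, phenotype TSV, YAML config; the
end-to-end pipeline lives here too.

All writers are deterministic (no timestamps) and stamp a provenance block
(config hash, seed, package version) into every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    apply_genomic_control,
    evaluate_power,
    run_null_phenotype,
    run_null_snp,
)
from .data import GenotypeMatrix, PhenotypeTable, align
from .errors import StageError, ValidationError
from .meta import classify_uniformity, fit_meta_regression
from .prs import build_prs, stratified_cqr_mr
from .regression import (
    DEFAULT_COVARIATES,
    QuantileGrid,
    filter_variants,
    fit_cqr,
    fit_ols,
    orient_risk_alleles,
)
from .simulate import (
    SimulationConfig,
    VariantSpec,
    compute_avmse,
    simulate_cohort,
)

log = logging.getLogger("cqrmeta")

PHENO_EYE_COLUMNS = ("sphere_right", "cyl_right", "sphere_left", "cyl_left")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_genotypes_vcf(genos: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with GT records; dosages hard-called by rounding."""
    path = Path(path)
    chrom = genos.chrom if genos.chrom is not None else ["1"] * genos.n_variants
    pos = genos.pos if genos.pos is not None else np.arange(1, genos.n_variants + 1)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in genos.individual_ids)
            + "\n"
        )
        for j in range(genos.n_variants):
            calls = []
            for d in genos.dosages[:, j]:
                calls.append("./." if np.isnan(d) else gt_map[float(np.round(d))])
            fh.write(
                f"{chrom[j]}\t{int(pos[j])}\t{genos.variant_ids[j]}\t"
                f"{genos.other_allele[j]}\t{genos.effect_allele[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Parse a GT-based VCF into additive ALT dosages.

    Multiallelic records are skipped with a warning; missing genotypes are
    mean-imputed with the per-variant missing rate recorded.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    dosage_cols, vids, ref, alt, chroms, poss, missing_rates = [], [], [], [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic record {variant.ID or variant.POS} in {path}"
            )
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = variant.gt_types.astype(float)
        col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        miss = np.isnan(col)
        rate = miss.mean()
        if miss.all():
            warnings.warn(f"skipping all-missing record {variant.ID}")
            continue
        if miss.any():
            col[miss] = col[~miss].mean()
        dosage_cols.append(col)
        vids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        ref.append(variant.REF)
        alt.append(variant.ALT[0])
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        missing_rates.append(rate)
    if not dosage_cols:
        raise ValidationError(f"no usable biallelic variants in {path}")
    return GenotypeMatrix(
        individual_ids=np.array(samples, dtype=object),
        variant_ids=np.array(vids, dtype=object),
        dosages=np.column_stack(dosage_cols),
        effect_allele=np.array(alt, dtype=object),
        other_allele=np.array(ref, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=int),
        missing_rate=np.array(missing_rates),
    )


def write_genotypes_tsv(genos: GenotypeMatrix, dosage_path, variants_path) -> None:
    """Dosage TSV (individuals x variants) plus an orientation-explicit
    variants TSV carrying the counted allele."""
    df = pd.DataFrame(genos.dosages, columns=list(genos.variant_ids))
    df.insert(0, "individual_id", genos.individual_ids)
    df.to_csv(dosage_path, sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "variant_id": genos.variant_ids,
            "counted_allele": genos.effect_allele,
            "other_allele": genos.other_allele,
            "chrom": genos.chrom if genos.chrom is not None else "1",
            "pos": genos.pos if genos.pos is not None else np.arange(1, genos.n_variants + 1),
        }
    )
    meta.to_csv(variants_path, sep="\t", index=False)


def read_genotypes_tsv(dosage_path, variants_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t")
    if "individual_id" not in df.columns:
        raise ValidationError(f"{dosage_path}: missing individual_id column")
    meta = pd.read_csv(variants_path, sep="\t", dtype={"variant_id": str})
    if "counted_allele" not in meta.columns:
        raise ValidationError(f"{variants_path}: counted_allele column is mandatory")
    vids = [c for c in df.columns if c != "individual_id"]
    if not vids:
        raise ValidationError(f"{dosage_path}: no variant columns")
    meta = meta.set_index("variant_id")
    missing = [v for v in vids if v not in meta.index]
    if missing:
        raise ValidationError(f"variants without metadata rows: {missing[:5]}")
    meta = meta.loc[vids]
    dosages = df[vids].to_numpy(dtype=float)
    miss = np.isnan(dosages)
    rates = miss.mean(axis=0)
    if miss.any():
        col_means = np.nanmean(dosages, axis=0)
        dosages = np.where(miss, col_means[None, :], dosages)
    return GenotypeMatrix(
        individual_ids=df["individual_id"].astype(str).to_numpy(dtype=object),
        variant_ids=np.array(vids, dtype=object),
        dosages=dosages,
        effect_allele=meta["counted_allele"].to_numpy(dtype=object),
        other_allele=meta["other_allele"].to_numpy(dtype=object),
        chrom=meta["chrom"].astype(str).to_numpy(dtype=object) if "chrom" in meta else None,
        pos=meta["pos"].to_numpy(dtype=int) if "pos" in meta else None,
        missing_rate=rates,
    )


def read_genotypes(path, fmt: str = "vcf", variants_path=None) -> GenotypeMatrix:
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    if fmt == "dosage_tsv":
        if variants_path is None:
            variants_path = Path(str(path)).with_suffix(".variants.tsv")
        return read_genotypes_tsv(path, variants_path)
    raise ValidationError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path) -> PhenotypeTable:
    """Typed phenotype table from TSV.

    If no ``trait`` column is present but per-eye sphere/cylinder columns
    are, the trait is computed as the mean spherical equivalent.  Rows with
    missing trait are dropped (count logged); duplicate ids are a hard error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "individual_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'individual_id'")
    if "trait" not in df.columns:
        if all(c in df.columns for c in PHENO_EYE_COLUMNS):
            df["trait"] = compute_avmse(
                df["sphere_right"], df["cyl_right"], df["sphere_left"], df["cyl_left"]
            )
        else:
            raise ValidationError(
                f"{path}: missing required column 'trait' "
                f"(or the eye columns {PHENO_EYE_COLUMNS})"
            )
    n_missing = int(df["trait"].isna().sum())
    if n_missing:
        log.info("dropping %d rows with missing trait", n_missing)
        df = df[df["trait"].notna()]
    df["individual_id"] = df["individual_id"].astype(str)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a pipeline run needs; ``seed`` is mandatory."""

    seed: int
    outdir: str = "results"
    genotypes: Optional[str] = None
    genotype_format: str = "vcf"
    variants_file: Optional[str] = None
    phenotypes: Optional[str] = None
    risk_allele_table: Optional[str] = None
    simulate: Optional[dict] = None
    grid: object = 9  # int name or explicit list of quantiles
    n_boot: int = 200
    se_method: str = "asymptotic"
    covariates: List[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    min_hom: int = 50
    alpha: float = 0.05
    calibration: Optional[dict] = None  # n_perm, n_snps, maf_range
    power: Optional[dict] = None  # sizes, reps
    prs: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        self.quantile_grid()  # validates
        if (self.genotypes is None) != (self.phenotypes is None):
            raise ValidationError("provide both genotypes and phenotypes, or neither")
        if self.genotypes is None and self.simulate is None:
            raise ValidationError("either input paths or a simulate block is required")

    def quantile_grid(self) -> QuantileGrid:
        if isinstance(self.grid, int):
            return QuantileGrid.named(self.grid)
        return QuantileGrid(tuple(self.grid))

    def validate_paths(self) -> None:
        for p in (self.genotypes, self.phenotypes, self.risk_allele_table, self.variants_file):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # outdir does not affect results and is excluded so relocated runs hash equal
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def simulation_config_from_dict(block: dict, seed: int) -> SimulationConfig:
    variants = [VariantSpec(**v) for v in block.get("variants", [])]
    kwargs = {k: v for k, v in block.items() if k != "variants"}
    kwargs.setdefault("seed", seed)
    return SimulationConfig(variants=variants, **kwargs)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _provenance(config: RunConfig) -> dict:
    return {
        "package": "cqrmeta",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def _write_tsv(df: pd.DataFrame, path, provenance: dict) -> None:
    with open(path, "w") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_inputs(config: RunConfig) -> Tuple[GenotypeMatrix, PhenotypeTable]:
    if config.simulate is not None:
        sim = simulation_config_from_dict(config.simulate, config.seed)
        return simulate_cohort(sim)
    config.validate_paths()
    genos = read_genotypes(
        config.genotypes, fmt=config.genotype_format, variants_path=config.variants_file
    )
    pheno = read_phenotypes(config.phenotypes)
    return align(genos, pheno)


def run_pipeline(config: RunConfig) -> dict:
    """Orient, filter, fit OLS + CQR + meta-regression per variant, calibrate,
    optionally measure power and the stratified score profile; write the
    result bundle under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    grid = config.quantile_grid()
    bundle: dict = {"provenance": prov}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, str(exc)) from exc

        return deco

    @stage("load")
    def _load():
        bundle["genos"], bundle["pheno"] = load_inputs(config)

    @stage("orient_filter")
    def _orient():
        genos = orient_risk_alleles(bundle["genos"], bundle["pheno"])
        genos, report = filter_variants(genos, min_hom=config.min_hom)
        bundle["genos"] = genos
        bundle["filter_report"] = report

    genos: GenotypeMatrix = bundle["genos"]
    pheno: PhenotypeTable = bundle["pheno"]
    covariates = [c for c in config.covariates if c in pheno.df.columns]

    @stage("fit")
    def _fit():
        ols_rows, cqr_rows, results = [], [], []
        for j, vid in enumerate(genos.variant_ids):
            dosage = genos.dosages[:, j]
            ols = fit_ols(pheno, dosage, covariates, variant_id=str(vid))
            ols_rows.append(dataclasses.asdict(ols))
            eff = fit_cqr(
                pheno,
                dosage,
                covariates=covariates,
                grid=grid,
                n_boot=config.n_boot,
                seed=config.seed + j,
                se_method=config.se_method,
                variant_id=str(vid),
            )
            for r in eff.records:
                cqr_rows.append(
                    {"variant_id": vid, "q": r.q, "beta_q": r.beta, "se_q": r.se,
                     "n_boot": r.n_boot, "ok": r.ok}
                )
            results.append(fit_meta_regression(eff))
        bundle["ols"] = pd.DataFrame(ols_rows)
        bundle["cqr"] = pd.DataFrame(cqr_rows)
        bundle["meta_results"] = results

    @stage("calibrate")
    def _calibrate():
        if not config.calibration:
            bundle["lambdas"] = np.ones(3)
            return
        cal = config.calibration
        n_snps = int(cal.get("n_snps", 500))
        maf_range = tuple(cal.get("maf_range", (0.05, 0.45)))
        null_snp = run_null_snp(
            pheno, n_snps, maf_range=maf_range, grid=grid, covariates=covariates,
            seed=config.seed + 7001, se_method=config.se_method,
        )
        bundle["null_snp_report"] = null_snp
        lam = null_snp.lambdas()
        bundle["lambdas"] = lam
        if cal.get("n_perm"):
            bundle["null_phenotype_report"] = run_null_phenotype(
                genos, pheno, int(cal["n_perm"]), grid=grid, covariates=covariates,
                seed=config.seed + 7002, se_method=config.se_method,
            )
        bundle["meta_results"] = [
            apply_genomic_control(r, lam) for r in bundle["meta_results"]
        ]

    @stage("classify")
    def _classify():
        n_var = max(genos.n_variants, 1)
        rows = []
        for res in bundle["meta_results"]:
            rows.append(
                {
                    "variant_id": res.variant_id,
                    "beta0": res.beta[0], "se0": res.se[0],
                    "ci0_low": res.ci_low[0], "ci0_high": res.ci_high[0], "p0": res.p[0],
                    "beta1": res.beta[1], "se1": res.se[1],
                    "ci1_low": res.ci_low[1], "ci1_high": res.ci_high[1], "p1": res.p[1],
                    "beta2": res.beta[2], "se2": res.se[2],
                    "ci2_low": res.ci_low[2], "ci2_high": res.ci_high[2], "p2": res.p[2],
                    "tau2": res.tau2,
                    "corrected": res.corrected,
                    "class": classify_uniformity(res, config.alpha, n_var),
                }
            )
        bundle["meta"] = pd.DataFrame(rows)

    @stage("power")
    def _power():
        if not config.power:
            return
        curve = evaluate_power(
            genos,
            pheno,
            sample_sizes=[int(s) for s in config.power["sizes"]],
            n_reps=int(config.power.get("reps", 20)),
            alpha=config.alpha,
            grid=grid,
            covariates=covariates,
            lambdas=bundle["lambdas"],
            seed=config.seed + 7003,
            se_method=config.se_method,
        )
        bundle["power_curve"] = curve

    @stage("prs")
    def _prs():
        if not config.prs:
            return
        score = build_prs(genos)
        bundle["prs_result"] = stratified_cqr_mr(
            pheno, score, grid=grid, covariates=covariates,
            seed=config.seed + 7004, se_method=config.se_method,
            n_boot=config.n_boot,
        )

    @stage("write")
    def _write():
        _write_tsv(bundle["ols"], outdir / "ols.tsv", prov)
        _write_tsv(bundle["cqr"], outdir / "cqr.tsv", prov)
        _write_tsv(bundle["meta"], outdir / "meta.tsv", prov)
        report = {"provenance": prov, "lambdas": [float(v) for v in bundle["lambdas"]]}
        if "null_snp_report" in bundle:
            report["null_snp"] = bundle["null_snp_report"].to_dict(config.alpha)
        if "null_phenotype_report" in bundle:
            report["null_phenotype"] = bundle["null_phenotype_report"].to_dict(config.alpha)
        with open(outdir / "calibration.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        if "power_curve" in bundle:
            pdict = bundle["power_curve"].to_dict()
            pdict["provenance"] = prov
            with open(outdir / "power.json", "w") as fh:
                json.dump(pdict, fh, indent=2, sort_keys=True)
        if "prs_result" in bundle:
            rows = []
            for prof in bundle["prs_result"].profiles:
                lo, hi = prof.ci()
                for k, q in enumerate(prof.quantiles):
                    rows.append(
                        {"stratum": prof.stratum, "n": prof.n, "q": q,
                         "beta_q": prof.beta[k], "se_q": prof.se[k],
                         "ci_low": lo[k], "ci_high": hi[k]}
                    )
            _write_tsv(pd.DataFrame(rows), outdir / "prs_profiles.tsv", prov)
            _write_tsv(bundle["prs_result"].contrasts, outdir / "prs_contrasts.tsv", prov)
    return bundle
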