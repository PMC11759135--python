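"""Readers, writers, run configuration and the end-to-end pipeline.

Genotypes are accepted as a VCF (per-sample GT, biallelic sites only;
dosage counts ALT alleles, ``./.`` is missing) or as a tab-delimited dosage
matrix (header row of marker ids, first column sample id, ``NA`` missing).
Phenotypes travel as CSV with columns sample_id, one column per trait,
milk_status and birth_year. The pipeline chains simulate/read -> QC ->
relationship matrix -> REML -> cross-validation -> report tables, and logs
every seed into a manifest so a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import MISSING_DOSAGE, GenotypeMatrix, PhenotypeTable, RelationshipMatrix
from .evaluation import cross_validate, descriptive_stats, make_folds
from .kinship import allele_frequencies, blend, vanraden_g
from .mixedmodel import fit_reml, genetic_correlation, heritability
from .qc import sample_qc, variant_qc
from .simdata import SimConfig, simulate_genotypes, simulate_phenotypes

logger = logging.getLogger("caprigen")


def read_genotypes(path, fmt: str = "auto") -> GenotypeMatrix:
    """Load genotypes from a VCF or a tab-delimited dosage matrix."""
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if "".join(path.suffixes).endswith((".vcf", ".vcf.gz")) else "dosage"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage":
        return _read_dosage_matrix(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in VCF header")
    marker_ids, rows, masks, meta = [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        gt = np.asarray(v.gt_types, dtype=np.int16)
        miss = gt == 3
        gt[miss] = MISSING_DOSAGE
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        marker_ids.append(mid)
        rows.append(gt)
        masks.append(miss)
        meta.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    meta_df = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"],
                           index=pd.Index(marker_ids, name="marker_id"))
    return GenotypeMatrix(sample_ids, marker_ids,
                          np.column_stack(rows), np.column_stack(masks), meta_df)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only, unphased VCF."""
    meta = genotypes.marker_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=caprigen {__version__}\n")
        for chrom in dict.fromkeys(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_DOSAGE: "./."}
        for j, mid in enumerate(genotypes.marker_ids):
            row = meta.iloc[j]
            calls = "\t".join(gt_str[int(d)] for d in genotypes.dosages[:, j])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{mid}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n")


def _read_dosage_matrix(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in dosage matrix")
    dosages = df.to_numpy(dtype=float)
    missing = np.isnan(dosages)
    bad = ~np.isin(dosages[~missing], (0, 1, 2))
    if bad.any():
        raise ValueError("dosage matrix entries must be 0, 1, 2 or NA")
    dosages = np.nan_to_num(dosages, nan=MISSING_DOSAGE).astype(np.int16)
    return GenotypeMatrix([str(s) for s in df.index],
                          [str(m) for m in df.columns], dosages, missing)


def write_dosage_matrix(genotypes: GenotypeMatrix, path) -> None:
    x = genotypes.dosage_float()
    df = pd.DataFrame(x, index=pd.Index(genotypes.sample_ids, name="sample_id"),
                      columns=genotypes.marker_ids)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_phenotypes(path, trait_names: list[str] | None = None) -> PhenotypeTable:
    """Load the phenotype CSV; collapse duplicate ids, drop incomplete rows."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "milk_status", "birth_year"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"phenotype file missing columns: {sorted(missing_cols)}")
    if trait_names is None:
        reserved = required | {"birth_year"}
        trait_names = [c for c in df.columns
                       if c not in reserved and not c.startswith("tbv_")]
    n_raw = len(df)
    df = df.drop_duplicates(subset="sample_id", keep="first")
    n_dup = n_raw - len(df)
    check_cols = [*trait_names, "milk_status", "birth_year"]
    complete = df[check_cols].notna().all(axis=1)
    n_incomplete = int((~complete).sum())
    df = df[complete]
    if n_dup or n_incomplete:
        logger.info("phenotypes: dropped %d duplicate and %d incomplete of %d "
                    "records (%.0f%% retained)", n_dup, n_incomplete, n_raw,
                    100.0 * len(df) / n_raw)
    df = df.set_index("sample_id")
    df["birth_year"] = df["birth_year"].astype(str)
    tbv_cols = [c for c in df.columns if c.startswith("tbv_")]
    tbv = None
    if tbv_cols:
        tbv = df[tbv_cols].rename(columns=lambda c: c[len("tbv_"):])
    return PhenotypeTable(df.drop(columns=tbv_cols), list(trait_names), tbv)


def write_phenotypes(phenos: PhenotypeTable, path) -> None:
    df = phenos.data.copy()
    if phenos.true_breeding_values is not None:
        for c in phenos.true_breeding_values.columns:
            df[f"tbv_{c}"] = phenos.true_breeding_values[c]
    df.to_csv(path, index_label="sample_id")


def write_grm(G: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(G.values, index=G.sample_ids, columns=G.sample_ids)
    with open(path, "w") as fh:
        fh.write(f"# denominator={G.denominator!r} blend_weight={G.blend_weight!r}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_grm(path) -> RelationshipMatrix:
    with open(path) as fh:
        header = fh.readline()
        parts = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return RelationshipMatrix(
        [str(s) for s in df.index], df.to_numpy(dtype=float),
        float(parts["denominator"]), float(parts["blend_weight"]),
    )


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulate or load, then evaluate)."""

    genotypes_path: str | None = None
    genotypes_format: str = "auto"
    phenotypes_path: str | None = None
    simulation: SimConfig | None = None
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_dev_max: float = 0.15
    blend_weight: float = 0.95
    methods: list[str] = field(default_factory=lambda: ["gblup", "krr", "adaboost_rt"])
    k_folds: int = 10
    seed: int = 0
    krr_alpha: float = 1.0
    adaboost_phi: float = 0.1
    n_estimators: int = 100
    out_dir: str = "caprigen_out"

    def __post_init__(self) -> None:
        has_files = self.genotypes_path is not None and self.phenotypes_path is not None
        if has_files == (self.simulation is not None):
            raise ValueError(
                "exactly one of {input paths, simulation block} must be given"
            )
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        for nm in ("call_rate_min", "maf_min", "hwe_dev_max"):
            v = getattr(self, nm)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{nm} outside [0, 1]")
        if not (0.0 < self.blend_weight <= 1.0):
            raise ValueError("blend_weight outside (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("genetic_cov", "residual_cov", "trait_means"):
                if key in sim:
                    sim[key] = np.asarray(sim[key], dtype=float)
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            sim = SimConfig(**sim)
        return cls(simulation=sim, **raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full evaluation and write the output bundle.

    Produces descriptive statistics (Table-1 shape), the genetic-parameter
    matrix (heritabilities on the diagonal, genetic correlations above,
    phenotypic correlations below — Table-2 shape), the per-method CV
    accuracy table with improvement percentages, and a manifest of seeds,
    versions and record counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"caprigen_version": __version__, "seed": config.seed,
                      "stages": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    # --- data
    s = stage("data")
    if config.simulation is not None:
        genos = simulate_genotypes(config.simulation)
        phenos = simulate_phenotypes(genos, config.simulation)
        s["source"] = "simulation"
        s["sim_seed"] = config.simulation.seed
    else:
        genos = read_genotypes(config.genotypes_path, config.genotypes_format)
        phenos = read_phenotypes(config.phenotypes_path)
        s["source"] = {"genotypes": str(config.genotypes_path),
                       "phenotypes": str(config.phenotypes_path)}
    shared = [sid for sid in genos.sample_ids if sid in set(phenos.sample_ids)]
    genos = genos.subset(sample_idx=[genos.sample_ids.index(x) for x in shared])
    phenos = phenos.subset(shared)
    s["n_samples"], s["n_markers"] = genos.n_samples, genos.n_markers

    # --- qc
    s = stage("qc")
    genos, vrep = variant_qc(genos, config.call_rate_min, config.maf_min,
                             config.hwe_dev_max)
    genos, srep = sample_qc(genos, config.call_rate_min)
    phenos = phenos.subset(genos.sample_ids)
    s["variant"] = json.loads(vrep.to_json())
    s["sample"] = json.loads(srep.to_json())
    (out / "qc_report.json").write_text(
        json.dumps({"variant": s["variant"], "sample": s["sample"]}, indent=2))

    # --- kinship
    s = stage("kinship")
    freqs = allele_frequencies(genos)
    G = blend(vanraden_g(genos, freqs), config.blend_weight)
    s["denominator"] = G.denominator
    s["blend_weight"] = G.blend_weight
    write_grm(G, out / "grm.tsv")

    # --- descriptive statistics (Table-1 shape)
    desc = pd.DataFrame({tr: descriptive_stats(phenos, tr)
                         for tr in phenos.trait_names})
    desc.to_csv(out / "table1_descriptives.csv")

    # --- genetic parameters (Table-2 shape)
    s = stage("reml")
    vc = fit_reml(phenos, G)
    s["converged"] = vc.converged
    s["n_iterations"] = vc.n_iterations
    s["reml_loglik"] = vc.reml_loglik
    t = vc.n_traits
    table2 = np.zeros((t, t))
    pheno_corr = np.corrcoef(
        np.column_stack([phenos.values(tr) for tr in vc.trait_names]), rowvar=False)
    pheno_corr = np.atleast_2d(pheno_corr)
    for i in range(t):
        table2[i, i] = heritability(vc, i)
        for j in range(i + 1, t):
            try:
                table2[i, j] = genetic_correlation(vc, i, j)
            except ZeroDivisionError:  # boundary estimate, correlation undefined
                table2[i, j] = float("nan")
            table2[j, i] = pheno_corr[i, j]
    pd.DataFrame(table2, index=vc.trait_names, columns=vc.trait_names).to_csv(
        out / "table2_genetic_parameters.csv", float_format="%.4f")
    vc_json = {
        "genetic_cov": vc.genetic_cov.tolist(),
        "residual_cov": vc.residual_cov.tolist(),
        "trait_names": vc.trait_names,
        "heritability": [heritability(vc, i) for i in range(t)],
        "converged": vc.converged,
    }
    (out / "variance_components.json").write_text(json.dumps(vc_json, indent=2))

    # --- cross-validation
    s = stage("cv")
    folds = make_folds(phenos.sample_ids, k=config.k_folds, seed=config.seed)
    report = cross_validate(
        config.methods, phenos, G, folds,
        krr_alpha=config.krr_alpha, adaboost_phi=config.adaboost_phi,
        n_estimators=config.n_estimators,
    )
    report.folds.to_csv(out / "cv_folds.csv", index=False)
    summary = report.summary()
    summary.to_csv(out / "cv_accuracy.csv", index=False, float_format="%.6f")
    (out / "cv_accuracy.json").write_text(
        json.dumps(summary.to_dict(orient="records"), indent=2))
    # method x trait accuracy table (bar-chart-shaped comparison)
    summary.pivot(index="method", columns="trait", values="mean_accuracy").to_csv(
        out / "accuracy_by_method.csv", float_format="%.4f")
    if "gblup" in config.methods and len(config.methods) > 1:
        report.improvements("gblup").to_csv(out / "cv_improvement.csv", index=False)
    s["k"] = config.k_folds

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"genotypes": genos, "phenotypes": phenos, "grm": G,
            "variance_components": vc, "cv_report": report,
            "descriptives": desc, "manifest": manifest, "out_dir": out}
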