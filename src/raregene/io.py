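"""Readers and writers for the package's tab-separated interchange formats,
plus minimal VCF export and cyvcf2-based VCF ingestion.

TSV is the canonical format: a genotype matrix (rows = individuals, columns =
SNPs, values 0/1/2) with a SNP-metadata sidecar (snp_id, gene, maf,
annotation), a covariate table, one phenotype table per replicate, and a
ground-truth effects table.  VCF is ingestion-only convenience; genotype
positions are irrelevant to every computation here, so SNP identity is by ID.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import (
    ANNOTATIONS, CovariateTable, GenotypeMatrix, PhenotypeSet, SimTruth, TRAITS,
)

logger = logging.getLogger(__name__)


def _individual_ids(n: int) -> list[str]:
    return [f"IND{i + 1:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# genotypes

def write_genotypes(geno: GenotypeMatrix, path: str | Path, meta_path: str | Path) -> None:
    df = pd.DataFrame(geno.counts, columns=geno.snp_ids,
                      index=_individual_ids(geno.n_individuals))
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")
    geno.snp_meta.to_csv(meta_path, sep="\t", index=False)


def read_genotypes(
    path: str | Path,
    format: str = "tsv",
    meta_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from TSV (with metadata sidecar) or VCF."""
    if format == "tsv":
        if meta_path is None:
            raise ParameterError("TSV genotypes need a metadata sidecar (meta_path)")
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy()
        bad = ~np.isin(counts, [0, 1, 2])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParameterError(
                f"invalid genotype value {counts[i, j]!r} at data row {i + 1}, "
                f"column {df.columns[j]!r} in {path}"
            )
        meta = pd.read_csv(meta_path, sep="\t", float_precision="round_trip")
        if list(meta["snp_id"]) != list(df.columns):
            raise ParameterError("metadata SNP order does not match genotype columns")
        anno = _clean_annotation(meta["annotation"])
        return GenotypeMatrix(
            counts=counts.astype(np.int8),
            snp_ids=meta["snp_id"].to_numpy(object),
            gene_of=meta["gene"].to_numpy(object),
            maf=meta["maf"].to_numpy(float),
            annotation=anno,
        )
    if format == "vcf":
        return _read_vcf(path)
    raise ParameterError(f"unknown genotype format: {format!r}")


def _clean_annotation(col: pd.Series) -> np.ndarray:
    vals = col.fillna("unknown").astype(str).str.strip().str.lower()
    out = []
    for v in vals:
        if v in ANNOTATIONS:
            out.append(v)
        else:
            logger.warning("unknown annotation label %r mapped to 'unknown'", v)
            out.append("unknown")
    return np.array(out, dtype=object)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal GT-only VCF export: one pseudo-contig, ALT is the minor allele
    by construction, gene/annotation carried in INFO (GENE, ANNO)."""
    ids = _individual_ids(geno.n_individuals)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        fh.write('##INFO=<ID=ANNO,Number=1,Type=String,Description="Functional annotation">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for j, snp in enumerate(geno.snp_ids):
            info = f"GENE={geno.gene_of[j]};ANNO={geno.annotation[j]}"
            gts = "\t".join(gt_codes[int(c)] for c in geno.counts[:, j])
            fh.write(f"1\t{j + 1}\t{snp}\tA\tT\t.\t.\t{info}\tGT\t{gts}\n")


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    snp_ids, genes, annos, cols = [], [], [], []
    for var in vcf:
        alt = np.zeros(len(vcf.samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            alt[i] = sum(1 for a in g[:-1] if a == 1)
        freq = alt.mean() / 2.0
        counts = alt if freq <= 0.5 else (2 - alt)  # count the minor allele
        cols.append(counts)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        genes.append(var.INFO.get("GENE") or "unknown_gene")
        annos.append(var.INFO.get("ANNO") or "unknown")
    counts = np.column_stack(cols).astype(np.int8)
    maf = counts.mean(axis=0) / 2.0
    return GenotypeMatrix(
        counts=counts,
        snp_ids=np.array(snp_ids, dtype=object),
        gene_of=np.array(genes, dtype=object),
        maf=maf,
        annotation=_clean_annotation(pd.Series(annos)),
    )


# ---------------------------------------------------------------------------
# covariates / phenotypes / truth / results

def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    out = cov.table.copy()
    out.insert(0, "individual_id", _individual_ids(len(out)))
    out.to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return CovariateTable(df[["age", "sex", "smoke", "population"]].copy())


def write_phenotypes(pheno: PhenotypeSet, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ids = _individual_ids(pheno.n_individuals)
    for k, rep in enumerate(pheno.replicates):
        out = rep.copy()
        out.insert(0, "individual_id", ids)
        out.to_csv(d / f"pheno_rep{k + 1:03d}.tsv", sep="\t", index=False)


def read_phenotypes(directory: str | Path) -> PhenotypeSet:
    d = Path(directory)
    files = sorted(d.glob("pheno_rep*.tsv"))
    if not files:
        raise ParameterError(f"no phenotype replicate files found under {d}")
    reps = [pd.read_csv(f, sep="\t", float_precision="round_trip")[["affected", "q1", "q2", "q4"]]
            for f in files]
    return PhenotypeSet(replicates=reps)


def write_truth(truth: SimTruth, path: str | Path, twin_path: str | Path | None = None) -> None:
    rows = [
        {"snp_id": s, "trait": t, "beta": b}
        for t, eff in truth.effects.items()
        for s, b in eff.items()
    ]
    pd.DataFrame(rows, columns=["snp_id", "trait", "beta"]).to_csv(path, sep="\t", index=False)
    if twin_path is not None:
        pd.DataFrame(
            [{"twin_snp": a, "causal_snp": b} for a, b in truth.twin_map.items()],
            columns=["twin_snp", "causal_snp"],
        ).to_csv(twin_path, sep="\t", index=False)


def read_truth(path: str | Path, twin_path: str | Path | None = None) -> SimTruth:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    truth = SimTruth()
    for t, sub in df.groupby("trait"):
        truth.effects[str(t)] = pd.Series(sub["beta"].to_numpy(float),
                                          index=sub["snp_id"].to_numpy(object))
    if twin_path is not None and Path(twin_path).exists():
        tw = pd.read_csv(twin_path, sep="\t")
        truth.twin_map = dict(zip(tw["twin_snp"].astype(str), tw["causal_snp"].astype(str)))
    return truth


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[],
                       dtype={"flags": str}, float_precision="round_trip")


__all__ = [
    "write_genotypes", "read_genotypes", "write_vcf",
    "write_covariates", "read_covariates",
    "write_phenotypes", "read_phenotypes",
    "write_truth", "read_truth", "write_results", "read_results",
]
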