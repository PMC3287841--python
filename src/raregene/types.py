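"""Core data containers for gene-level rare-variant association analysis.

The containers mirror the tabular layout of a mini-exome study of unrelated
individuals: a fixed genotype matrix of minor-allele counts with per-SNP gene
membership, minor allele frequency (MAF) and functional annotation; a table of
environmental covariates; replicated phenotype tables drawn on those fixed
genotypes; and a ground-truth record of the simulated causal architecture.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError

#: annotation labels; anything else is coerced to "unknown" on ingestion
ANNOTATIONS = ("nonsynonymous", "synonymous", "unknown")

#: trait names used throughout
TRAITS = ("q1", "q2", "q4", "affected")

#: default MAF cutoff below which a variant is "rare"
RARE_MAF = 0.05


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs minor-allele count matrix with per-SNP metadata.

    Attributes
    ----------
    counts
        ``(n, m)`` integer array with values in {0, 1, 2}; entry ``(i, l)``
        is the number of minor alleles individual ``i`` carries at SNP ``l``.
    snp_ids
        length-``m`` array of unique SNP identifiers.
    gene_of
        length-``m`` array mapping each SNP to its (single) gene.
    maf
        length-``m`` array of minor allele frequencies in [0, 0.5], equal to
        the empirical frequency of the counts.
    annotation
        length-``m`` array with values in :data:`ANNOTATIONS`.
    """

    counts: np.ndarray
    snp_ids: np.ndarray
    gene_of: np.ndarray
    maf: np.ndarray
    annotation: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.gene_of = np.asarray(self.gene_of, dtype=object)
        self.maf = np.asarray(self.maf, dtype=float)
        self.annotation = np.asarray(self.annotation, dtype=object)
        self._gene_cols: dict[str, np.ndarray] | None = None
        self._snp_index: dict[str, int] | None = None

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def genes(self) -> list[str]:
        """Gene identifiers in first-appearance order."""
        return list(dict.fromkeys(self.gene_of))

    def gene_columns(self, gene: str) -> np.ndarray:
        """Column indices of the SNPs belonging to ``gene``."""
        if self._gene_cols is None:
            cols: dict[str, list[int]] = {}
            for j, g in enumerate(self.gene_of):
                cols.setdefault(g, []).append(j)
            self._gene_cols = {g: np.asarray(j) for g, j in cols.items()}
        try:
            return self._gene_cols[gene]
        except KeyError:
            raise ParameterError(f"unknown gene: {gene!r}") from None

    def snp_index(self, snp_id: str) -> int:
        if self._snp_index is None:
            self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise ParameterError(f"unknown SNP: {snp_id!r}") from None

    @property
    def snp_meta(self) -> pd.DataFrame:
        """Per-SNP metadata table (snp_id, gene, maf, annotation)."""
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "gene": self.gene_of,
                "maf": self.maf,
                "annotation": self.annotation,
            }
        )

    @property
    def is_monomorphic(self) -> np.ndarray:
        """Boolean mask of SNPs with no minor-allele carriers."""
        return self.maf == 0.0

    def validate(self) -> None:
        """Check the container invariants; raise ParameterError on violation."""
        n, m = self.counts.shape
        if not (len(self.snp_ids) == len(self.gene_of) == len(self.maf) == len(self.annotation) == m):
            raise ParameterError("metadata arrays must have one entry per SNP")
        if len(set(self.snp_ids)) != m:
            raise ParameterError("snp_ids must be unique")
        vals = np.unique(self.counts)
        if not np.all(np.isin(vals, [0, 1, 2])):
            raise ParameterError("genotype counts must be in {0, 1, 2}")
        if np.any((self.maf < 0) | (self.maf > 0.5)):
            raise ParameterError("maf must lie in [0, 0.5]")
        emp = self.counts.mean(axis=0) / 2.0
        emp = np.minimum(emp, 1.0 - emp)
        if np.any(np.abs(emp - self.maf) > 1.0 / (2 * n) + 1e-12):
            raise ParameterError("stored maf inconsistent with counts")
        bad = set(self.annotation) - set(ANNOTATIONS)
        if bad:
            raise ParameterError(f"unknown annotation labels: {sorted(bad)}")

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            counts=self.counts.copy(),
            snp_ids=self.snp_ids.copy(),
            gene_of=self.gene_of.copy(),
            maf=self.maf.copy(),
            annotation=self.annotation.copy(),
        )


@dataclass
class CovariateTable:
    """Environmental covariates: Age (years), Sex and Smoke (0/1 indicators)
    and Population (categorical, reference-coded for modeling)."""

    table: pd.DataFrame  # columns: age, sex, smoke, population

    def __post_init__(self) -> None:
        missing = {"age", "sex", "smoke", "population"} - set(self.table.columns)
        if missing:
            raise ParameterError(f"covariate table missing columns: {sorted(missing)}")

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    def design_matrix(self, add_intercept: bool = True) -> np.ndarray:
        """Numeric design matrix: intercept (optional), age, sex, smoke, then
        reference-coded population indicators (first level dropped)."""
        cols = [self.table["age"].to_numpy(float),
                self.table["sex"].to_numpy(float),
                self.table["smoke"].to_numpy(float)]
        pop = self.table["population"].astype(str)
        levels = sorted(pop.unique())
        for lev in levels[1:]:  # drop the first level as reference
            cols.append((pop == lev).to_numpy(float))
        X = np.column_stack(cols) if cols else np.empty((len(self.table), 0))
        if add_intercept:
            X = np.column_stack([np.ones(len(self.table)), X])
        return X

    def design_columns(self, add_intercept: bool = True) -> list[str]:
        pop = self.table["population"].astype(str)
        levels = sorted(pop.unique())
        names = ["age", "sex", "smoke"] + [f"population[{lev}]" for lev in levels[1:]]
        return (["intercept"] + names) if add_intercept else names


@dataclass
class SimTruth:
    """Ground truth of a simulated causal architecture.

    ``effects[trait]`` maps causal SNP id -> signed effect size on the trait
    scale (per minor allele).  ``architecture[trait]`` holds the target
    (genetic, environmental, residual) variance fractions.  ``twin_map`` maps
    each injected noncausal "genotype twin" SNP to the causal SNP whose column
    it copies.
    """

    effects: dict[str, "pd.Series"] = field(default_factory=dict)
    architecture: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    twin_map: dict[str, str] = field(default_factory=dict)

    def causal_snps(self, trait: str) -> list[str]:
        eff = self.effects.get(trait)
        return [] if eff is None else list(eff.index)

    def causal_genes(self, geno: GenotypeMatrix, trait: str) -> set[str]:
        """A gene is causal for a trait iff it contains >= 1 causal SNP."""
        return {geno.gene_of[geno.snp_index(s)] for s in self.causal_snps(trait)}

    def copy(self) -> "SimTruth":
        return SimTruth(
            effects={t: s.copy() for t, s in self.effects.items()},
            architecture=dict(self.architecture),
            twin_map=dict(self.twin_map),
        )


@dataclass
class PhenotypeSet:
    """R phenotype replicates on fixed genotypes and covariates.

    Each replicate is a DataFrame with columns ``affected`` (0/1) and the
    quantitative traits ``q1``, ``q2``, ``q4``, one row per individual.
    """

    replicates: list[pd.DataFrame]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def n_individuals(self) -> int:
        return len(self.replicates[0])

    def trait_matrix(self, trait: str) -> np.ndarray:
        """``(n, R)`` array of one trait across replicates."""
        if trait not in TRAITS:
            raise ParameterError(f"unknown trait: {trait!r}")
        return np.column_stack([rep[trait].to_numpy(float) for rep in self.replicates])


@dataclass
class GeneScore:
    """Per-individual genetic score(s) for one gene.

    ``values`` is ``(n,)`` for single-score methods or ``(n, 2)`` for the
    two-group CMC variant, with ``columns`` naming the score columns.
    """

    gene: str
    values: np.ndarray
    method: str
    columns: tuple[str, ...] = ("score",)
    n_snps_used: int = 0

    def as_matrix(self) -> np.ndarray:
        v = np.asarray(self.values, dtype=float)
        return v[:, None] if v.ndim == 1 else v


@dataclass
class GeneTestResult:
    """Outcome of one gene-level association test."""

    gene: str
    method: str
    statistic: float
    p_value: float
    n_snps_used: int
    df: float | None = None          # burden tests: LRT degrees of freedom
    kappa: float | None = None       # kernel tests: scale of the chi-square
    nu: float | None = None          # kernel tests: effective df
    flags: tuple[str, ...] = ()

    def to_row(self) -> dict:
        return {
            "gene": self.gene,
            "method": self.method,
            "n_snps_used": self.n_snps_used,
            "statistic": self.statistic,
            "df": "" if self.df is None else self.df,
            "kappa": "" if self.kappa is None else self.kappa,
            "nu": "" if self.nu is None else self.nu,
            "p_value": self.p_value,
            "flags": ";".join(self.flags),
        }


def results_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    """Collect test results into the canonical results table."""
    return pd.DataFrame([r.to_row() for r in results])


__all__ = [
    "ANNOTATIONS", "TRAITS", "RARE_MAF",
    "GenotypeMatrix", "CovariateTable", "SimTruth", "PhenotypeSet",
    "GeneScore", "GeneTestResult", "results_frame", "replace",
]
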