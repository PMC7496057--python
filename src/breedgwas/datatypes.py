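"""Core in-memory containers.

A cohort is held as a :class:`GenotypeMatrix`: a samples x SNPs dosage matrix
(minor-allele counts 0/1/2, ``NaN`` for missing) together with the SNP map and
the per-sample breed labels. Breed-level phenotypes and gene sets travel as
plain :class:`pandas.DataFrame` objects with fixed column schemas, validated by
the helpers below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Chromosome labels treated as non-autosomal under the dog (CanFam) convention:
#: 38 autosomes, so "39" is the X-linked pseudo-label used by array releases.
NON_AUTOSOMES = frozenset({"39", "X", "Y", "XY", "MT", "M"})

PHENOTYPE_COLUMNS = ("breed", "body_weight_kg", "life_expectancy_years", "cancer_mortality_pct")
GENE_COLUMNS = ("gene", "chrom", "start", "end")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with map and breed labels.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array with entries in {0, 1, 2} or NaN
        for missing genotypes. Dosage counts the minor allele as defined on
        the sample set the matrix was built from.
    snps
        One row per SNP: columns ``snp`` (unique id), ``chrom`` (string
        label), ``pos`` (1-based bp), ``a1`` (counted/minor allele), ``a2``.
    samples
        One row per sample: columns ``sample`` (unique id), ``breed``.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.dosages.ndim != 2:
            raise SchemaError("dosages must be a 2-D samples x SNPs matrix")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise SchemaError(f"sample table has {len(self.samples)} rows for {n} matrix rows")
        if len(self.snps) != m:
            raise SchemaError(f"snp map has {len(self.snps)} rows for {m} matrix columns")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise SchemaError("non-missing dosages must be 0, 1 or 2")
        for col in ("snp", "chrom", "pos", "a1", "a2"):
            if col not in self.snps.columns:
                raise SchemaError(f"snp map missing required column '{col}'")
        for col in ("sample", "breed"):
            if col not in self.samples.columns:
                raise SchemaError(f"sample table missing required column '{col}'")
        if self.snps["snp"].duplicated().any():
            dup = self.snps["snp"][self.snps["snp"].duplicated()].iloc[0]
            raise SchemaError(f"duplicate SNP id '{dup}'")
        if self.samples["sample"].duplicated().any():
            dup = self.samples["sample"][self.samples["sample"].duplicated()].iloc[0]
            raise SchemaError(f"duplicate sample id '{dup}'")
        if self.samples["breed"].isna().any() or (self.samples["breed"].astype(str) == "").any():
            raise SchemaError("every sample needs a breed label")
        pos = self.snps["pos"].to_numpy()
        if (pos < 1).any():
            raise SchemaError("SNP positions must be positive 1-based integers")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def breeds(self) -> np.ndarray:
        """Unique breed labels, sorted."""
        return np.sort(self.samples["breed"].unique())

    def breed_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each breed's samples."""
        return {b: np.flatnonzero((self.samples["breed"] == b).to_numpy()) for b in self.breeds}

    def take_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[rows], self.snps.copy(), self.samples.iloc[rows])

    def take_snps(self, cols: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, cols], self.snps.iloc[cols], self.samples.copy())

    def drop_snps(self, snp_ids) -> "GenotypeMatrix":
        keep = ~self.snps["snp"].isin(list(snp_ids)).to_numpy()
        return self.take_snps(np.flatnonzero(keep))

    def snp_index(self, snp_ids) -> np.ndarray:
        """Column indices for the given SNP ids (raises on unknown ids)."""
        lookup = pd.Index(self.snps["snp"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise SchemaError(f"SNP ids absent from the genotype map: {missing[:10]}")
        return idx

    def is_autosomal(self) -> np.ndarray:
        """Boolean mask of autosomal SNPs (dog convention)."""
        return ~self.snps["chrom"].astype(str).isin(NON_AUTOSOMES).to_numpy()


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check a breed phenotype table against its invariants and return it.

    Required columns: breed, body_weight_kg, life_expectancy_years,
    cancer_mortality_pct. Breeds must be unique, weights positive and cancer
    mortality within [0, 100]. Optional standardized-residual columns (any
    column ending in ``_residual``) must have mean ~0 and SD ~1.
    """
    for col in PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"phenotype table missing required column '{col}'")
    if df["breed"].duplicated().any():
        dup = df["breed"][df["breed"].duplicated()].iloc[0]
        raise SchemaError(f"duplicated breed row '{dup}' in phenotype table")
    if (df["body_weight_kg"] <= 0).any():
        raise SchemaError("body_weight_kg must be positive")
    cm = df["cancer_mortality_pct"]
    if ((cm < 0) | (cm > 100)).any():
        raise SchemaError("cancer_mortality_pct must lie in [0, 100]")
    for col in df.columns:
        if col.endswith("_residual"):
            v = df[col].to_numpy(dtype=float)
            if abs(v.mean()) > 1e-8 or abs(v.std(ddof=1) - 1.0) > 1e-8:
                raise SchemaError(f"residual column '{col}' is not standardized (mean 0, SD 1)")
    return df


def validate_gene_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-interval table (gene, chrom, start, end; 1-based inclusive)."""
    for col in GENE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"gene table missing required column '{col}'")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate gene id '{dup}'")
    bad = df[df["start"] > df["end"]]
    if len(bad):
        raise SchemaError(f"gene '{bad['gene'].iloc[0]}' has start > end")
    if (df["start"] < 1).any():
        raise SchemaError("gene coordinates are 1-based; start must be >= 1")
    return df


@dataclass
class PermutationNull:
    """Distribution of the per-permutation minimum raw P over all tested SNPs."""

    n_perm: int
    min_p: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.min_p = np.asarray(self.min_p, dtype=float)
        if self.min_p.shape != (self.n_perm,):
            raise SchemaError("min_p must have length n_perm")
        if ((self.min_p <= 0) | (self.min_p > 1)).any():
            raise SchemaError("permutation minima must lie in (0, 1]")


@dataclass
class StageResult:
    """Book-keeping for one QC stage."""

    name: str
    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    n_snps_out: int
    removed_snps: list = field(default_factory=list)


@dataclass
class QCReport:
    """Telescoping record of the QC cascade."""

    stages: list[StageResult] = field(default_factory=list)
    seed: int | None = None

    def add(self, stage: StageResult) -> None:
        if self.stages:
            prev = self.stages[-1]
            if (stage.n_samples_in, stage.n_snps_in) != (prev.n_samples_out, prev.n_snps_out):
                raise SchemaError(
                    f"stage '{stage.name}' input does not telescope from '{prev.name}' output"
                )
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "samples_in": s.n_samples_in,
                    "samples_out": s.n_samples_out,
                    "snps_in": s.n_snps_in,
                    "snps_out": s.n_snps_out,
                    "snps_removed": s.n_snps_in - s.n_snps_out,
                }
                for s in self.stages
            ]
        )
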