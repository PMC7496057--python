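"""Breed-structured cohort simulator.

Generates genotype/phenotype data with the statistical structure an
across-breed association scan assumes: many small closed breeding populations
with strong between-breed allele-frequency differentiation, and breed-level
traits (body weight, life expectancy at age 4, cancer mortality) in which
weight correlates positively with cancer mortality and negatively with
lifespan.

Between-breed divergence follows the Balding–Nichols model: for a SNP with
ancestral frequency ``p``, each breed draws its own frequency from
``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
``F * p * (1-p)`` with ``F`` the ``differentiation`` parameter. Genotypes are
then binomial draws within breed (no within-breed pedigree structure), and an
optional set of exactly duplicated SNPs provides perfect-LD pairs for pruning
tests. Traits are affine in breed weight plus Gaussian noise; planted SNP
effects add ``effect * (breed-mean dosage)`` to a named trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .errors import ConfigError, MappingError

_BASES = np.array(list("ACGT"))

#: Trait names accepted for planted effects. The ``*_residual`` names express
#: the effect in residual-SD units (multiples of the trait's noise SD), which
#: is the natural scale for effects meant to survive covariate adjustment.
PLANTABLE_TRAITS = ("cancer_mortality", "life_expectancy", "cancer_residual", "longevity_residual")


@dataclass
class PlantedEffect:
    """A causal SNP effect: ``effect`` trait units per breed-mean dosage unit."""

    snp_index: int
    trait: str
    effect: float


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study design this pipeline targets: 63 pedigree
    breeds capped at a few tens of samples each, biallelic autosomal SNPs with
    moderate between-breed differentiation, and breed-level phenotypes whose
    weight–cancer correlation is positive and weight–lifespan correlation is
    negative.
    """

    n_breeds: int = 63
    samples_per_breed: int | Sequence[int] = 20
    n_snps: int = 3000
    n_chromosomes: int = 39  # 38 autosomes + one sex chromosome labelled "39"
    differentiation: float = 0.2
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    weight_range: tuple[float, float] = (5.0, 70.0)
    slope_lifespan_per_kg: float = -0.07
    slope_cancer_per_kg: float = 0.35
    lifespan_intercept: float = 13.5
    cancer_intercept: float = 20.0
    noise_sd_lifespan: float = 1.4
    noise_sd_cancer: float = 11.0
    duplicate_snps: int = 0
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_effects = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(*e) for e in self.planted_effects
        ]
        self.validate()

    def validate(self) -> None:
        for name in ("n_breeds", "n_snps", "n_chromosomes"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if not (0.0 <= self.differentiation < 1.0):
            raise ConfigError("differentiation must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("ancestral_maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.weight_range[0] <= 0 or self.weight_range[0] > self.weight_range[1]:
            raise ConfigError("weight_range must be a positive increasing pair")
        if self.duplicate_snps < 0:
            raise ConfigError("duplicate_snps must be non-negative")
        if self.noise_sd_lifespan < 0 or self.noise_sd_cancer < 0:
            raise ConfigError("noise_sd_lifespan and noise_sd_cancer must be non-negative")
        counts = self.samples_counts()
        if min(counts) < 1:
            raise ConfigError("samples_per_breed entries must be positive")
        for eff in self.planted_effects:
            if not (0 <= eff.snp_index < self.n_snps):
                raise ConfigError(f"planted_effects snp index {eff.snp_index} >= n_snps")
            if eff.trait not in PLANTABLE_TRAITS:
                raise ConfigError(
                    f"planted_effects trait '{eff.trait}' not one of {PLANTABLE_TRAITS}"
                )

    def samples_counts(self) -> list[int]:
        if np.isscalar(self.samples_per_breed):
            return [int(self.samples_per_breed)] * self.n_breeds
        counts = [int(c) for c in self.samples_per_breed]
        if len(counts) != self.n_breeds:
            raise ConfigError("samples_per_breed list length must equal n_breeds")
        return counts

    def breed_labels(self) -> list[str]:
        return [f"breed_{i + 1:02d}" for i in range(self.n_breeds)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # named substreams so genotypes/phenotypes are independently reproducible
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a breed-structured dosage matrix under the Balding–Nichols model.

    Deterministic for a fixed ``config.seed``. Dosages are reoriented after
    sampling so that they count the minor allele of the realized sample (ties
    at frequency 0.5 broken toward the lexicographically smaller allele),
    matching the orientation convention of the PLINK text reader.
    """
    rng = _rng(config, 0)
    counts = config.samples_counts()
    n_samples = sum(counts)
    F = config.differentiation

    p_anc = rng.uniform(*config.ancestral_maf_range, size=config.n_snps)
    if F == 0.0:
        breed_freq = np.tile(p_anc, (config.n_breeds, 1))
    else:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        breed_freq = rng.beta(a, b, size=(config.n_breeds, config.n_snps))

    per_sample_freq = np.repeat(breed_freq, counts, axis=0)
    dosages = rng.binomial(2, per_sample_freq).astype(float)

    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan

    # SNP map: contiguous chromosome blocks, strictly increasing positions
    chrom_of = np.sort(rng.integers(0, config.n_chromosomes, size=config.n_snps)) + 1
    gaps = rng.integers(1, 60_000, size=config.n_snps)
    pos = np.empty(config.n_snps, dtype=int)
    for c in range(1, config.n_chromosomes + 1):
        block = chrom_of == c
        pos[block] = np.cumsum(gaps[block])
    allele_pairs = np.array([(i, j) for i in range(4) for j in range(4) if i != j])
    pick = allele_pairs[rng.integers(0, len(allele_pairs), size=config.n_snps)]
    snps = pd.DataFrame(
        {
            "snp": [f"snp_{i + 1:06d}" for i in range(config.n_snps)],
            "chrom": chrom_of.astype(str),
            "pos": pos,
            "a1": _BASES[pick[:, 0]],
            "a2": _BASES[pick[:, 1]],
        }
    )

    if config.duplicate_snps > 0:
        # exact copies placed immediately after their source -> r^2 = 1 pairs
        src = np.sort(rng.choice(config.n_snps, size=config.duplicate_snps, replace=False))
        order = np.sort(np.concatenate([np.arange(config.n_snps), src + 0.5]))
        take = order.astype(int)
        dosages = dosages[:, take]
        snps = snps.iloc[take].reset_index(drop=True)
        dup_rows = order != take  # the inserted half-index rows
        ids = snps["snp"].to_numpy(dtype=object)
        ids[dup_rows] = [f"{s}_dup" for s in ids[dup_rows]]
        snps["snp"] = ids
        snps.loc[dup_rows, "pos"] = snps.loc[dup_rows, "pos"] + 1

    dosages, snps = orient_to_minor(dosages, snps)

    breeds = np.repeat(config.breed_labels(), counts)
    samples = pd.DataFrame(
        {
            "sample": [f"{b}_s{i:03d}" for b, n in zip(config.breed_labels(), counts) for i in range(1, n + 1)],
            "breed": breeds,
        }
    )
    return GenotypeMatrix(dosages, snps, samples)


def orient_to_minor(dosages: np.ndarray, snps: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip dosage columns so each counts the sample minor allele.

    Ties (allele frequency exactly 0.5) resolve to the lexicographically
    smaller allele as "minor". Returns the (possibly modified) matrix and map.
    """
    n_obs = (~np.isnan(dosages)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(dosages, axis=0) / (2.0 * n_obs)  # per-SNP allele-1 frequency
    freq[n_obs == 0] = np.nan  # all-missing column: leave orientation alone
    a1 = snps["a1"].to_numpy(dtype=object)
    a2 = snps["a2"].to_numpy(dtype=object)
    flip = (freq > 0.5) | ((freq == 0.5) & (a1 > a2))
    if flip.any():
        dosages = dosages.copy()
        dosages[:, flip] = 2.0 - dosages[:, flip]
        snps = snps.copy()
        snps.loc[flip, ["a1", "a2"]] = np.stack([a2[flip], a1[flip]], axis=1)
    return dosages, snps


def simulate_phenotypes(config: SimulationConfig, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Draw breed-level phenotypes (one row per breed).

    ``life_expectancy_years`` and ``cancer_mortality_pct`` are affine in body
    weight plus Gaussian noise; planted effects add
    ``effect * breed-mean dosage`` to the named trait (``*_residual`` names
    scale the effect by the trait's noise SD) before cancer mortality is
    clamped to [0, 100].
    """
    labels = config.breed_labels()
    geno_breeds = sorted(genotypes.samples["breed"].unique())
    if geno_breeds != sorted(labels):
        raise MappingError("genotype matrix breed labels inconsistent with config")

    rng = _rng(config, 1)
    nb = config.n_breeds
    weight = rng.uniform(*config.weight_range, size=nb)
    life = (
        config.lifespan_intercept
        + config.slope_lifespan_per_kg * weight
        + rng.normal(0.0, config.noise_sd_lifespan, size=nb)
    )
    cancer = (
        config.cancer_intercept
        + config.slope_cancer_per_kg * weight
        + rng.normal(0.0, config.noise_sd_cancer, size=nb)
    )

    if config.planted_effects:
        order = {b: i for i, b in enumerate(labels)}
        rows_of = genotypes.breed_indices()
        for eff in config.planted_effects:
            col = genotypes.snp_index([f"snp_{eff.snp_index + 1:06d}"])[0]
            mean_dose = np.full(nb, np.nan)
            for b, rows in rows_of.items():
                vals = genotypes.dosages[rows, col]
                vals = vals[~np.isnan(vals)]
                if vals.size:
                    mean_dose[order[b]] = vals.mean()
            mean_dose = np.nan_to_num(mean_dose, nan=0.0)
            if eff.trait == "cancer_mortality":
                cancer += eff.effect * mean_dose
            elif eff.trait == "life_expectancy":
                life += eff.effect * mean_dose
            elif eff.trait == "cancer_residual":
                cancer += eff.effect * config.noise_sd_cancer * mean_dose
            elif eff.trait == "longevity_residual":
                life += eff.effect * config.noise_sd_lifespan * mean_dose

    cancer = np.clip(cancer, 0.0, 100.0)
    return pd.DataFrame(
        {
            "breed": labels,
            "body_weight_kg": weight,
            "life_expectancy_years": life,
            "cancer_mortality_pct": cancer,
        }
    )


def simulate_gene_set(
    genotypes: GenotypeMatrix,
    n_genes: int = 20,
    span_bp: int = 30_000,
    seed: int | None = None,
    prefix: str = "gene",
) -> pd.DataFrame:
    """A synthetic gene-interval table anchored on random SNPs of the map.

    Stands in for externally supplied candidate gene lists: each gene is a
    ``span_bp`` interval centred on a randomly chosen SNP, so candidate
    extraction is guaranteed to intersect the map. 1-based inclusive.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be a positive count")
    rng = np.random.default_rng(seed)
    anchors = rng.choice(genotypes.n_snps, size=min(n_genes, genotypes.n_snps), replace=False)
    rows = []
    for k, col in enumerate(np.sort(anchors), start=1):
        pos = int(genotypes.snps["pos"].iloc[col])
        rows.append(
            {
                "gene": f"{prefix}_{k:04d}",
                "chrom": str(genotypes.snps["chrom"].iloc[col]),
                "start": max(1, pos - span_bp // 2),
                "end": pos + span_bp // 2,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Run both generators and return (genotypes, phenotypes, truth table).

    The truth table records everything a validation run needs to audit:
    duplicated-SNP pairs (expected LD-prune removals) and planted effects.
    """
    geno = simulate_genotypes(config)
    pheno = simulate_phenotypes(config, geno)
    rows = []
    for s in geno.snps["snp"]:
        if s.endswith("_dup"):
            rows.append({"kind": "duplicate", "snp": s, "detail": s[: -len("_dup")], "effect": np.nan})
    for eff in config.planted_effects:
        rows.append(
            {
                "kind": "planted",
                "snp": f"snp_{eff.snp_index + 1:06d}",
                "detail": eff.trait,
                "effect": eff.effect,
            }
        )
    truth = pd.DataFrame(rows, columns=["kind", "snp", "detail", "effect"])
    return geno, pheno, truth
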