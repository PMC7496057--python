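"""Across-breed additive association with breed-structured max-T correction.

The model: every sample in a breed carries that breed's trait value, and each
SNP is tested by ordinary least squares of the trait on minor-allele dosage
(0/1/2) with an intercept — the additive genotypic model. Because breeds are
strongly differentiated, raw per-SNP P values are badly anti-conservative;
family-wise correction therefore uses a breed-randomised min-P (max-T)
permutation scheme: the breed->value assignment is permuted over whole breeds
(samples within a breed always share a value), the scan is re-run, and the
minimum raw P over all tested SNPs is recorded per permutation. The corrected
P of a SNP is

    (1 + #{permutations whose minimum raw P <= raw P}) / (n_perm + 1),

bounded below by 1/(n_perm + 1). SNPs with corrected P < 0.05 are tier
"significant", < 0.1 "marginal".

API follows the statsmodels convention: build a :class:`BreedGWAS` model from
a genotype matrix and a breed phenotype table, call :meth:`BreedGWAS.fit`,
and read estimates, the permutation null and ``summary()`` off the returned
:class:`BreedGWASResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, PermutationNull, validate_phenotypes
from .errors import ConfigError, DegenerateFitError, MappingError

logger = logging.getLogger("breedgwas.association")

_P_FLOOR = 1e-300  # numerically-perfect fits get a tiny positive P, never 0


def assign_breed_values(g: GenotypeMatrix, pheno: pd.DataFrame, column: str) -> np.ndarray:
    """Expand a per-breed trait column to a per-sample vector."""
    if column not in pheno.columns:
        raise MappingError(f"phenotype table has no column '{column}'")
    lookup = dict(zip(pheno["breed"], pheno[column]))
    breeds = g.samples["breed"]
    missing = sorted(set(breeds) - set(lookup))
    if missing:
        raise MappingError(f"breeds missing from the phenotype table: {missing}")
    return breeds.map(lookup).to_numpy(dtype=float)


def _masked_ols(dosages: np.ndarray, Y: np.ndarray) -> dict[str, np.ndarray]:
    """Closed-form per-SNP simple OLS for one or many trait vectors.

    ``dosages``: (n, m) with NaN missing; ``Y``: (n, k). Returns per-SNP
    arrays: beta/se/t/p of shape (m, k) and n_used (m,). Per-SNP case
    deletion: each SNP's fit uses only its non-missing samples. SNPs that are
    monomorphic among used samples, or have < 3 used samples, get NaN P.
    """
    M = ~np.isnan(dosages)
    G0 = np.where(M, dosages, 0.0)
    n = M.sum(axis=0).astype(float)  # (m,)
    Sx = G0.sum(axis=0)
    Sxx = (G0 * G0).sum(axis=0)
    Mf = M.astype(float)
    Sy = Mf.T @ Y  # (m, k)
    Syy = Mf.T @ (Y * Y)
    Sxy = G0.T @ Y

    with np.errstate(invalid="ignore", divide="ignore"):
        vx = Sxx - Sx * Sx / n  # (m,)
        cov = Sxy - (Sx / n)[:, None] * Sy
        vy = Syy - Sy * Sy / n[:, None]
        beta = cov / vx[:, None]
        sse = vy - beta * cov
        df = n - 2.0
        sigma2 = np.maximum(sse, 0.0) / df[:, None]
        se = np.sqrt(sigma2 / vx[:, None])
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df[:, None])

    bad = (n < 3)[:, None] | (vx <= 1e-12 * np.maximum(n, 1.0))[:, None] | (vy <= 0)
    p = np.clip(p, _P_FLOOR, 1.0)
    p[bad] = np.nan
    beta[bad] = np.nan
    se[bad] = np.nan
    t[bad] = np.nan
    return {"beta": beta, "se": se, "t": t, "p": p, "n_used": n.astype(int)}


def additive_association(g: GenotypeMatrix, trait_vector: np.ndarray) -> pd.DataFrame:
    """Per-SNP additive-model scan: slope, SE and two-sided Wald-t raw P.

    SNPs that are monomorphic after per-SNP case deletion (or have fewer than
    3 called samples) are emitted with raw_p absent and a logged warning.
    """
    y = np.asarray(trait_vector, dtype=float).reshape(-1, 1)
    if y.shape[0] != g.n_samples:
        raise MappingError("trait vector length must equal the number of samples")
    res = _masked_ols(g.dosages, y)
    n_skipped = int(np.isnan(res["p"][:, 0]).sum())
    if n_skipped:
        logger.warning("%d SNPs degenerate (monomorphic or < 3 samples): raw_p absent", n_skipped)
    return pd.DataFrame(
        {
            "snp": g.snps["snp"].to_numpy(),
            "chrom": g.snps["chrom"].to_numpy(),
            "pos": g.snps["pos"].to_numpy(),
            "n_used": res["n_used"],
            "beta": res["beta"][:, 0],
            "se": res["se"][:, 0],
            "raw_p": res["p"][:, 0],
        }
    )


def breed_permutation_null(
    g: GenotypeMatrix,
    pheno: pd.DataFrame,
    column: str,
    n_perm: int = 1000,
    seed: int | None = None,
    unit: str = "breed",
    batch: int = 128,
) -> PermutationNull:
    """Min-P permutation null for the across-breed scan.

    Each permutation draws a uniform random permutation of the breed->value
    map (identity included; duplicates across the ``n_perm`` draws allowed),
    assigns every sample its permuted breed value, re-runs the additive scan
    on all SNPs with the original missing-data pattern, and stores the
    minimum raw P. ``unit="sample"`` instead permutes trait values across
    individual samples — a deliberately miscalibrated control that ignores
    breed structure, kept for diagnostics only.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if unit not in ("breed", "sample"):
        raise ConfigError("unit must be 'breed' or 'sample'")
    values = assign_breed_values(g, pheno, column)
    breeds, breed_idx = np.unique(g.samples["breed"].to_numpy(), return_inverse=True)
    breed_values = np.array(
        [values[breed_idx == i][0] for i in range(len(breeds))], dtype=float
    )
    if len(breeds) < 2:
        raise ConfigError("breed permutation needs at least 2 breeds")

    rng = np.random.default_rng(seed)
    min_p = np.empty(n_perm)
    for start in range(0, n_perm, batch):
        b = min(batch, n_perm - start)
        if unit == "breed":
            perms = np.stack([rng.permutation(len(breeds)) for _ in range(b)], axis=1)
            Y = breed_values[perms][breed_idx]  # (n_samples, b)
        else:
            Y = np.stack([rng.permutation(values) for _ in range(b)], axis=1)
        p = _masked_ols(g.dosages, Y)["p"]
        if np.isnan(p).all(axis=0).any():
            raise DegenerateFitError(
                "a permutation produced no testable SNP (constant trait?)"
            )
        with np.errstate(invalid="ignore"):
            min_p[start : start + b] = np.nanmin(p, axis=0)
    return PermutationNull(n_perm=n_perm, min_p=min_p, seed=seed)


def corrected_p(raw_p, null: PermutationNull):
    """Max-T corrected P: ``(1 + #{min_p <= raw_p}) / (n_perm + 1)``.

    Ties count as exceedances (conservative). Accepts a scalar or vector;
    absent (NaN) raw P yields absent corrected P.
    """
    raw = np.asarray(raw_p, dtype=float)
    sorted_min = np.sort(null.min_p)
    counts = np.searchsorted(sorted_min, raw, side="right")
    out = (1.0 + counts) / (null.n_perm + 1.0)
    out = np.where(np.isnan(raw), np.nan, out)
    return float(out) if np.isscalar(raw_p) else out


def assign_tiers(corrected: np.ndarray, alpha: float = 0.05, marginal: float = 0.1) -> np.ndarray:
    """significant (< alpha, strict) / marginal (< marginal) / ns; absent -> 'na'."""
    c = np.asarray(corrected, dtype=float)
    tier = np.full(c.shape, "ns", dtype=object)
    tier[c < marginal] = "marginal"
    tier[c < alpha] = "significant"
    tier[np.isnan(c)] = "na"
    return tier


class BreedGWAS:
    """Across-breed additive association model for one breed-level trait.

    Parameters
    ----------
    genotypes
        QC'd :class:`GenotypeMatrix`.
    phenotypes
        Breed phenotype table; must contain ``trait`` and cover every breed
        present in ``genotypes``.
    trait
        Column of ``phenotypes`` to test (e.g. ``body_weight_kg``,
        ``cancer_residual``, ``longevity_residual``).
    candidates
        Optional iterable of SNP ids restricting the scan (e.g. SNPs near a
        candidate gene set); ids absent from the map raise an error listing
        them. Default: all SNPs.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        phenotypes: pd.DataFrame,
        trait: str,
        candidates=None,
        alpha: float = 0.05,
        marginal: float = 0.1,
    ) -> None:
        validate_phenotypes(phenotypes)
        if not (0.0 < alpha <= marginal < 1.0):
            raise ConfigError("need 0 < alpha <= marginal < 1")
        if candidates is not None:
            cols = genotypes.snp_index(list(candidates))
            genotypes = genotypes.take_snps(np.sort(cols))
        self.genotypes = genotypes
        self.phenotypes = phenotypes
        self.trait = trait
        self.alpha = alpha
        self.marginal = marginal
        self.trait_vector = assign_breed_values(genotypes, phenotypes, trait)

    def fit(self, n_perm: int = 1000, seed: int | None = None) -> "BreedGWASResults":
        """Run the scan and the breed-permutation correction."""
        table = additive_association(self.genotypes, self.trait_vector)
        null = breed_permutation_null(
            self.genotypes, self.phenotypes, self.trait, n_perm=n_perm, seed=seed
        )
        table["corrected_p"] = corrected_p(table["raw_p"].to_numpy(), null)
        table["tier"] = assign_tiers(table["corrected_p"].to_numpy(), self.alpha, self.marginal)
        return BreedGWASResults(model=self, table=table, null=null, seed=seed)


@dataclass
class BreedGWASResults:
    """Fitted across-breed scan: per-SNP estimates plus the permutation null."""

    model: BreedGWAS
    table: pd.DataFrame
    null: PermutationNull
    seed: int | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["tier"] == "significant"]

    @property
    def marginally_significant(self) -> pd.DataFrame:
        return self.table[self.table["tier"].isin(["significant", "marginal"])]

    def manhattan_table(self) -> pd.DataFrame:
        """Association table plus a cumulative genome x-coordinate."""
        t = self.table.copy()

        def _key(label):
            s = str(label)
            return (0, int(s)) if s.isdigit() else (1, s)

        offsets, running = {}, 0
        for chrom in sorted(t["chrom"].astype(str).unique(), key=_key):
            offsets[chrom] = running
            running += int(t.loc[t["chrom"].astype(str) == chrom, "pos"].max())
        t["genome_pos"] = [offsets[str(c)] + int(p) for c, p in zip(t["chrom"], t["pos"])]
        return t

    def summary(self, top: int = 10) -> str:
        m = self.model
        tested = int(self.table["raw_p"].notna().sum())
        lines = [
            "Across-breed additive association (breed-permutation corrected)",
            "=" * 64,
            f"Trait: {m.trait}",
            f"Samples: {m.genotypes.n_samples}   Breeds: {len(m.genotypes.breeds)}",
            f"SNPs: {m.genotypes.n_snps} ({m.genotypes.n_snps - tested} untestable)",
            f"Permutations: {self.null.n_perm}   Seed: {self.seed}",
            f"Significant (corrected P < {m.alpha:g}): {len(self.significant)}",
            f"Marginal (corrected P < {m.marginal:g}): "
            f"{len(self.marginally_significant) - len(self.significant)}",
            "-" * 64,
        ]
        show = self.table.dropna(subset=["raw_p"]).nsmallest(top, "raw_p")
        header = f"{'snp':<14}{'chrom':>6}{'pos':>12}{'beta':>10}{'raw_p':>12}{'corr_p':>9}  tier"
        lines.append(header)
        for r in show.itertuples(index=False):
            lines.append(
                f"{r.snp:<14}{r.chrom:>6}{r.pos:>12}{r.beta:>10.3f}"
                f"{r.raw_p:>12.3e}{r.corrected_p:>9.4f}  {r.tier}"
            )
        return "\n".join(lines)


def run_association_experiment(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    candidates=None,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    marginal: float = 0.1,
) -> BreedGWASResults:
    """One-call wrapper: build :class:`BreedGWAS` and fit it."""
    return BreedGWAS(
        genotypes, phenotypes, trait, candidates=candidates, alpha=alpha, marginal=marginal
    ).fit(n_perm=n_perm, seed=seed)
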