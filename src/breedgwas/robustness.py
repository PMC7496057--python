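"""Validation procedures for the across-breed scan.

Two independent checks of hit stability:

* subject-resampling robustness — repeatedly drop a fraction of samples at
  random, re-run the full association + permutation experiment, and count in
  how many repetitions each SNP keeps its significance tier;
* per-breed MAF/trait correlation — correlate each SNP's per-breed minor
  allele frequency with the per-breed trait (Pearson and Spearman) with
  Benjamini–Hochberg FDR over all tested SNPs, an association route that
  never touches individual genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import BreedGWASResults, run_association_experiment
from .datatypes import GenotypeMatrix
from .errors import ConfigError
from .qc import remove_fraction

logger = logging.getLogger("breedgwas.robustness")


@dataclass
class RobustnessResult:
    """Original fit, per-repetition fits, and the per-SNP stability summary."""

    original: BreedGWASResults
    replicates: list[BreedGWASResults]
    stability: pd.DataFrame


def resample_robustness(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    candidates=None,
    frac: float = 0.10,
    reps: int = 10,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    marginal: float = 0.1,
) -> RobustnessResult:
    """Subject-resampling stability of the association experiment.

    Each repetition removes ``floor(frac * n)`` samples uniformly at random
    (so 1274 samples at the default 10% leave 1147) and re-runs the full
    scan + permutation correction with the same permutation seed as the
    original run; ``frac=0`` therefore reproduces the original exactly. A
    repetition that empties a breed drops that breed with a logged warning.
    """
    if not (0.0 <= frac < 1.0):
        raise ConfigError("frac must lie in [0, 1)")
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    root = np.random.SeedSequence(seed)
    perm_seed = int(root.generate_state(1)[0] & 0x7FFFFFFF)
    original = run_association_experiment(
        genotypes, phenotypes, trait, candidates, n_perm, perm_seed, alpha, marginal
    )

    n = genotypes.n_samples
    n_keep = remove_fraction(n, frac)
    replicates: list[BreedGWASResults] = []
    for rep, child in enumerate(root.spawn(reps), start=1):
        rng = np.random.default_rng(child)
        rows = np.sort(rng.choice(n, size=n_keep, replace=False))
        sub = genotypes.take_samples(rows)
        dropped = set(genotypes.breeds) - set(sub.breeds)
        if dropped:
            logger.warning("repetition %d emptied breeds %s; dropped", rep, sorted(dropped))
        replicates.append(
            run_association_experiment(
                sub, phenotypes, trait, candidates, n_perm, perm_seed, alpha, marginal
            )
        )

    stab = original.table[["snp", "chrom", "pos", "tier"]].rename(columns={"tier": "original_tier"})
    sig = np.zeros(len(stab), dtype=int)
    marg = np.zeros(len(stab), dtype=int)
    for res in replicates:
        t = res.table.set_index("snp")["tier"].reindex(stab["snp"])
        sig += (t == "significant").to_numpy()
        marg += t.isin(["significant", "marginal"]).to_numpy()
    stab["reps_significant"] = sig
    stab["reps_marginal_or_better"] = marg
    stab["reps"] = reps
    return RobustnessResult(original=original, replicates=replicates, stability=stab)


def per_breed_maf(g: GenotypeMatrix) -> pd.DataFrame:
    """Breeds x SNPs frequency matrix of the globally-defined minor allele.

    Minor-allele orientation is fixed once on the whole cohort (the matrix's
    dosage coding), so per-breed values are comparable across breeds; a breed
    fixed for the global minor allele shows frequency 1.0. Cells where a
    breed has no called genotypes are NaN.
    """
    breeds = g.breeds
    out = np.full((len(breeds), g.n_snps), np.nan)
    for i, rows in enumerate(g.breed_indices().values()):
        d = g.dosages[rows]
        n_obs = (~np.isnan(d)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.nansum(d, axis=0) / (2.0 * n_obs)
        out[i] = np.where(n_obs == 0, np.nan, f)
    return pd.DataFrame(out, index=pd.Index(breeds, name="breed"), columns=g.snps["snp"])


def maf_trait_correlation(
    breed_maf: pd.DataFrame, trait_values: pd.Series, min_breeds: int = 3
) -> pd.DataFrame:
    """Per-SNP correlation of per-breed MAF with a per-breed trait.

    ``trait_values`` is indexed by breed. Uses pairwise-complete breeds per
    SNP; SNPs with fewer than ``min_breeds`` complete breeds, or a constant
    MAF vector, are skipped with a logged warning. Benjamini–Hochberg q-values
    are computed over all tested SNPs, separately for the Pearson and
    Spearman P vectors.
    """
    y_full = trait_values.reindex(breed_maf.index).to_numpy(dtype=float)
    rows = []
    skipped = 0
    for snp in breed_maf.columns:
        x_full = breed_maf[snp].to_numpy(dtype=float)
        m = ~(np.isnan(x_full) | np.isnan(y_full))
        x, y = x_full[m], y_full[m]
        if len(x) < min_breeds or np.all(x == x[0]) or np.all(y == y[0]):
            skipped += 1
            continue
        pr, pp = stats.pearsonr(x, y)
        sr, sp = stats.spearmanr(x, y)
        rows.append(
            {
                "snp": snp,
                "n_breeds": len(x),
                "pearson_r": pr,
                "pearson_p": pp,
                "spearman_rho": sr,
                "spearman_p": sp,
            }
        )
    if skipped:
        logger.warning("%d SNPs skipped (too few breeds or constant MAF)", skipped)
    out = pd.DataFrame(
        rows, columns=["snp", "n_breeds", "pearson_r", "pearson_p", "spearman_rho", "spearman_p"]
    )
    if len(out):
        out["pearson_q"] = bh_qvalues(out["pearson_p"].to_numpy())
        out["spearman_q"] = bh_qvalues(out["spearman_p"].to_numpy())
    else:
        out["pearson_q"] = out["spearman_q"] = np.nan
    return out


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (statsmodels ``fdr_bh``)."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ConfigError("P values for FDR must not contain NaN")
    return multipletests(p, method="fdr_bh")[1]


def lowest_correlations(corr_table: pd.DataFrame, k: int = 30, by: str = "spearman_p") -> pd.DataFrame:
    """Ranking report: the ``k`` SNPs with the lowest pre-FDR P values."""
    return corr_table.nsmallest(k, by).reset_index(drop=True)
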