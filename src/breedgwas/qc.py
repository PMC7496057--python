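"""Quality-control cascade for breed-structured genotype data.

Stages, applied in this order by :func:`run_qc`:

1. per-breed sample cap (breeds over the cap are randomly subsampled),
2. removal of non-autosomal SNPs,
3. per-SNP missingness filter (removed when missingness > threshold),
4. minor-allele-frequency filter (removed when MAF < threshold),
5. Hardy–Weinberg exact-test filter (removed when P < alpha),
6. within-chromosome sliding-window LD pruning (r^2 above threshold removes
   the SNP later in map order).

The HWE test is the exact conditional test: with allele counts fixed, the
two-sided P is the total probability of all heterozygote counts whose
probability does not exceed that of the observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import GenotypeMatrix, QCReport, StageResult
from .errors import ConfigError, QCStageError

logger = logging.getLogger("breedgwas.qc")


@dataclass
class QCConfig:
    """Thresholds of the QC cascade (defaults follow the study design)."""

    per_breed_cap: int = 30
    max_missing: float = 0.10
    min_maf: float = 0.01
    hwe_alpha: float = 0.01
    hwe_mode: str = "pooled"  # "pooled" (default) or "per_breed"
    ld_r2_max: float = 0.9
    ld_window_snps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_breed_cap < 1:
            raise ConfigError("per_breed_cap must be >= 1")
        for name in ("max_missing", "min_maf", "hwe_alpha", "ld_r2_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.hwe_mode not in ("pooled", "per_breed"):
            raise ConfigError("hwe_mode must be 'pooled' or 'per_breed'")
        if self.ld_window_snps < 2:
            raise ConfigError("ld_window_snps must be >= 2")


# ---------------------------------------------------------------------------
# per-stage primitives
# ---------------------------------------------------------------------------

def subsample_per_breed(g: GenotypeMatrix, cap: int, seed: int | None = None) -> GenotypeMatrix:
    """Reduce each breed to at most ``cap`` samples chosen uniformly at random.

    Breeds at or under the cap are retained whole. Deterministic per seed;
    surviving samples keep their original row order.
    """
    if cap < 1:
        raise ConfigError("per_breed_cap must be >= 1")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for breed in g.breeds:  # sorted, so the draw order is reproducible
        rows = np.flatnonzero((g.samples["breed"] == breed).to_numpy())
        if len(rows) > cap:
            rows = rng.choice(rows, size=cap, replace=False)
        keep.append(rows)
    return g.take_samples(np.sort(np.concatenate(keep)))


def snp_missingness(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP fraction of missing genotype cells."""
    return np.isnan(g.dosages).mean(axis=0)


def snp_maf(g: GenotypeMatrix, dosages: np.ndarray | None = None) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing dosages.

    Returns NaN for SNPs with no called genotypes.
    """
    d = g.dosages if dosages is None else dosages
    n_obs = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(d, axis=0) / (2.0 * n_obs)
    f = np.where(n_obs == 0, np.nan, f)
    return np.minimum(f, 1.0 - f)


@lru_cache(maxsize=100_000)
def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided Hardy–Weinberg exact test P for one SNP's genotype counts.

    Conditions on the allele counts: P is the summed probability of every
    heterozygote count at least as improbable as the observed one. Monomorphic
    SNPs have a single attainable configuration and return P = 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ConfigError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ConfigError("total genotype count must be positive")
    rare = n_het + 2 * min(n_hom1, n_hom2)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | n, rare): multinomial over genotypes / binomial over alleles
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, prob[prob <= obs * (1.0 + 1e-12)].sum()))


def genotype_counts(g: GenotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """(n_snps, 3) counts of dosage 0/1/2, optionally over a sample subset."""
    d = g.dosages if rows is None else g.dosages[rows]
    return np.stack([(d == k).sum(axis=0) for k in (0.0, 1.0, 2.0)], axis=1)


def hwe_pvalues(g: GenotypeMatrix, mode: str = "pooled") -> np.ndarray:
    """Per-SNP HWE exact P; ``per_breed`` mode returns each SNP's minimum
    P over breeds with any called genotypes (a stratified screen)."""
    if mode == "pooled":
        counts = genotype_counts(g)
        return np.array(
            [
                hwe_exact_test(int(c[0]), int(c[1]), int(c[2])) if c.sum() else np.nan
                for c in counts
            ]
        )
    pvals = np.ones(g.n_snps)
    for rows in g.breed_indices().values():
        counts = genotype_counts(g, rows)
        for j, c in enumerate(counts):
            if c.sum():
                pvals[j] = min(pvals[j], hwe_exact_test(int(c[0]), int(c[1]), int(c[2])))
    return pvals


def ld_r2(g: GenotypeMatrix, snp_a: int, snp_b: int) -> float:
    """Squared Pearson correlation of two dosage columns over jointly
    non-missing samples; NaN when either SNP is monomorphic there."""
    x = g.dosages[:, snp_a]
    y = g.dosages[:, snp_b]
    m = ~(np.isnan(x) | np.isnan(y))
    x, y = x[m], y[m]
    if len(x) < 2 or x.std() == 0.0 or y.std() == 0.0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _window_r2(d: np.ndarray, kept_cols: list[int], j: int) -> np.ndarray:
    """r^2 of column j against each kept column, pairwise-complete."""
    y = d[:, j]
    X = d[:, kept_cols]
    My = ~np.isnan(y)
    MX = ~np.isnan(X)
    M = MX & My[:, None]
    n = M.sum(axis=0).astype(float)
    X0 = np.where(M, X, 0.0)
    y0 = np.where(My, y, 0.0)
    Sx = X0.sum(axis=0)
    Sxx = (X0 * X0).sum(axis=0)
    Sy = (M * y0[:, None]).sum(axis=0)
    Syy = (M * (y0 * y0)[:, None]).sum(axis=0)
    Sxy = (X0 * y0[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (n * Sxy - Sx * Sy) ** 2
        den = (n * Sxx - Sx * Sx) * (n * Syy - Sy * Sy)
        r2 = num / den
    r2[(den <= 0) | (n < 2)] = np.nan
    return r2


def ld_prune(
    g: GenotypeMatrix, r2_max: float = 0.9, window_snps: int = 50
) -> tuple[GenotypeMatrix, list[str]]:
    """Greedy within-chromosome LD pruning.

    Scans SNPs in map order; a SNP is removed when its r^2 with any retained
    SNP at most ``window_snps - 1`` map positions earlier exceeds ``r2_max``
    (the later SNP of each offending pair is dropped). Pairs whose r^2 is
    undefined (a monomorphic member) are skipped with a logged warning.
    """
    snp_ids = g.snps["snp"].to_numpy()
    chroms = g.snps["chrom"].astype(str).to_numpy()
    removed: list[str] = []
    keep_mask = np.ones(g.n_snps, dtype=bool)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        kept: list[tuple[int, int]] = []  # (local index, global column)
        for local_j, j in enumerate(cols):
            window = [gi for li, gi in kept if local_j - li < window_snps]
            if window:
                r2 = _window_r2(g.dosages, window, j)
                if np.isnan(r2).any():
                    logger.warning(
                        "undefined r^2 (monomorphic member) for SNP '%s' on chrom %s",
                        snp_ids[j],
                        chrom,
                    )
                if np.any(r2 > r2_max):
                    keep_mask[j] = False
                    removed.append(snp_ids[j])
                    continue
            kept.append((local_j, j))
    return g.take_snps(np.flatnonzero(keep_mask)), removed


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def run_qc(g: GenotypeMatrix, config: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the full QC cascade and return the filtered cohort plus report."""
    config = config or QCConfig()
    report = QCReport(seed=config.seed)

    def stage(name: str, before: GenotypeMatrix, after: GenotypeMatrix, removed=()):
        report.add(
            StageResult(
                name,
                before.n_samples,
                after.n_samples,
                before.n_snps,
                after.n_snps,
                list(removed),
            )
        )
        if after.n_samples == 0 or after.n_snps == 0:
            raise QCStageError(f"QC stage '{name}' emptied the data set")

    g1 = subsample_per_breed(g, config.per_breed_cap, config.seed)
    stage("per_breed_cap", g, g1)

    auto = g1.is_autosomal()
    g2 = g1.take_snps(np.flatnonzero(auto))
    stage("autosomes", g1, g2, g1.snps["snp"].to_numpy()[~auto])

    miss = snp_missingness(g2)
    bad = miss > config.max_missing
    g3 = g2.take_snps(np.flatnonzero(~bad))
    stage("missingness", g2, g3, g2.snps["snp"].to_numpy()[bad])

    maf = snp_maf(g3)
    bad = np.isnan(maf) | (maf < config.min_maf)
    g4 = g3.take_snps(np.flatnonzero(~bad))
    stage("maf", g3, g4, g3.snps["snp"].to_numpy()[bad])

    hwe = hwe_pvalues(g4, config.hwe_mode)
    bad = hwe < config.hwe_alpha
    g5 = g4.take_snps(np.flatnonzero(~bad))
    stage("hwe", g4, g5, g4.snps["snp"].to_numpy()[bad])

    g6, removed = ld_prune(g5, config.ld_r2_max, config.ld_window_snps)
    stage("ld_prune", g5, g6, removed)

    return g6, report


def remove_fraction(n: int, frac: float) -> int:
    """Samples remaining after removing ``floor(frac * n)`` of ``n``."""
    if not (0.0 <= frac < 1.0):
        raise ConfigError("frac must lie in [0, 1)")
    return n - int(np.floor(frac * n))
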