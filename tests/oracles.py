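"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: exact rational
arithmetic for the Hardy-Weinberg test, naive double loops for correlations,
and explicit enumeration for the breed-permutation null.
"""

from fractions import Fraction
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats


def exact_hwe_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """HWE exact P by full enumeration with exact fractions.

    Conditional on allele counts: weight(h) = n! / (nAA! h! nBB!) * 2^h for
    each attainable heterozygote count h; P is the summed weight of all
    configurations no more probable than the observed one, over the total.
    """
    n = n_hom1 + n_het + n_hom2
    rare = n_het + 2 * min(n_hom1, n_hom2)

    def weight(h: int) -> int:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return factorial(n) // (factorial(hom_rare) * factorial(h) * factorial(hom_common)) * 2**h

    hets = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_het]
    return float(Fraction(sum(w for w in weights.values() if w <= obs), total))


def naive_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation by the definition, pairwise complete."""
    m = ~(np.isnan(x) | np.isnan(y))
    x, y = x[m], y[m]
    xc = x - x.mean()
    yc = y - y.mean()
    num = float((xc * yc).sum()) ** 2
    den = float((xc * xc).sum()) * float((yc * yc).sum())
    return num / den


def rank_then_correlate(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as Pearson on mid-ranks, computed independently."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float((rxc * ryc).sum() / np.sqrt((rxc**2).sum() * (ryc**2).sum()))


def exhaustive_breed_min_p(genotypes, breed_values: np.ndarray, breed_idx: np.ndarray):
    """Minimum raw P for every permutation of the breed->value assignment.

    Runs a plain per-SNP ``linregress`` for each of the n_breeds! complete
    assignments; only feasible for tiny breed counts.
    """
    mins = []
    d = genotypes.dosages
    for perm in permutations(range(len(breed_values))):
        y = breed_values[np.asarray(perm)][breed_idx]
        best = np.inf
        for j in range(d.shape[1]):
            x = d[:, j]
            m = ~np.isnan(x)
            if m.sum() < 3 or np.unique(x[m]).size < 2 or np.unique(y[m]).size < 2:
                continue
            best = min(best, stats.linregress(x[m], y[m]).pvalue)
        mins.append(best)
    return np.array(mins)


def bh_stepup(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values by the textbook step-up recursion."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q
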