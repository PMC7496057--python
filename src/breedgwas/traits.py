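"""Breed-level trait statistics: correlations, jackknife, residualization.

This layer reproduces the descriptive-statistics side of an across-breed
scan: Spearman rank correlations between the breed phenotypes, a jackknife
bias-corrected correlation estimate to gauge outlier influence, and
standardized OLS residuals that make cancer mortality and longevity
analysable independently of body weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import validate_phenotypes
from .errors import DegenerateFitError, InsufficientDataError


@dataclass
class CorrelationResult:
    """A rank correlation with its two-sided P and optional jackknife estimate."""

    rho: float
    p_value: float
    n: int
    jackknife_estimate: float | None = None


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    r: float
    p_value: float


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length 1-D vectors")
    if len(x) < min_n:
        raise InsufficientDataError(f"need at least {min_n} observations, got {len(x)}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InsufficientDataError("missing values are not allowed here")
    return x, y


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson on mid-ranks, two-sided P from the
    t-approximation with n-2 degrees of freedom."""
    x, y = _check_pair(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateFitError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), len(x))


def leave_one_out_spearman(x, y) -> np.ndarray:
    """The n leave-one-out Spearman rhos; their spread flags influential points."""
    x, y = _check_pair(x, y, min_n=4)
    n = len(x)
    loo = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        loo[i] = stats.spearmanr(x[mask], y[mask])[0]
        mask[i] = True
    return loo


def jackknife_correlation(x, y) -> float:
    """Bias-corrected jackknife of the Spearman correlation.

    With theta-hat the full-sample rho and theta-bar the mean of the n
    leave-one-out rhos, returns ``n * theta_hat - (n - 1) * theta_bar``.
    """
    x, y = _check_pair(x, y, min_n=4)
    n = len(x)
    full = spearman(x, y).rho
    loo = leave_one_out_spearman(x, y)
    return float(n * full - (n - 1) * loo.mean())


def spearman_with_jackknife(x, y) -> CorrelationResult:
    res = spearman(x, y)
    res.jackknife_estimate = jackknife_correlation(x, y)
    return res


def linear_fit(x, y) -> LinearFitResult:
    """Ordinary least squares of y on x (scipy ``linregress`` semantics)."""
    x, y = _check_pair(x, y)
    fit = stats.linregress(x, y)
    return LinearFitResult(float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue))


def residualize(trait, *covariates, studentized: bool = False) -> np.ndarray:
    """Standardized residuals of an OLS fit of ``trait`` on the covariates.

    Fits with an intercept and divides the raw residuals by their sample
    standard deviation (n-1 denominator), so the output has mean 0 and SD 1.
    ``studentized=True`` returns internally studentized (leverage-adjusted)
    residuals instead.
    """
    y = np.asarray(trait, dtype=float)
    X = np.column_stack([np.asarray(c, dtype=float) for c in covariates])
    if len(y) <= X.shape[1] + 1:
        raise InsufficientDataError("need more observations than covariates + 1")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateFitError("collinear covariates: design matrix is rank-deficient")
    fit = sm.OLS(y, design).fit()
    resid = fit.resid
    sd = resid.std(ddof=1)
    if sd < 1e-12 * max(1.0, np.abs(y).max()):
        raise DegenerateFitError("zero residual variance: trait is an exact function of covariates")
    if studentized:
        from statsmodels.stats.outliers_influence import OLSInfluence

        return np.asarray(OLSInfluence(fit).resid_studentized_internal)
    return np.asarray(resid / sd)


# ---------------------------------------------------------------------------
# phenotype-table level operations
# ---------------------------------------------------------------------------

#: residual columns added by :func:`add_residual_traits` and what they adjust for
RESIDUAL_COLUMNS = {
    "cancer_weight_residual": ("cancer_mortality_pct", ("body_weight_kg",)),
    "cancer_residual": ("cancer_mortality_pct", ("body_weight_kg", "life_expectancy_years")),
    "longevity_residual": ("life_expectancy_years", ("body_weight_kg",)),
}


def add_residual_traits(pheno: pd.DataFrame) -> pd.DataFrame:
    """Augment a breed phenotype table with its standardized residual traits.

    Adds ``cancer_weight_residual`` (cancer mortality adjusted for weight
    only, the descriptive-analysis residual), ``cancer_residual`` (adjusted
    for weight and life expectancy, the association-analysis residual) and
    ``longevity_residual`` (life expectancy adjusted for weight). The two
    cancer residuals are kept under distinct names to avoid conflation.
    """
    validate_phenotypes(pheno)
    out = pheno.copy()
    for col, (trait, covs) in RESIDUAL_COLUMNS.items():
        out[col] = residualize(
            out[trait].to_numpy(), *[out[c].to_numpy() for c in covs]
        )
    return out


def correlation_report(pheno: pd.DataFrame) -> pd.DataFrame:
    """All pairwise trait correlations of the descriptive analysis.

    One row per pair: Spearman rho, two-sided P, n, and the jackknife
    bias-corrected estimate; plus a Pearson linear-fit row for cancer
    mortality on body weight.
    """
    p = add_residual_traits(pheno) if "cancer_weight_residual" not in pheno.columns else pheno
    pairs = [
        ("body_weight_kg", "cancer_mortality_pct"),
        ("body_weight_kg", "life_expectancy_years"),
        ("life_expectancy_years", "cancer_mortality_pct"),
        ("life_expectancy_years", "cancer_weight_residual"),
    ]
    rows = []
    for a, b in pairs:
        res = spearman_with_jackknife(p[a].to_numpy(), p[b].to_numpy())
        rows.append(
            {
                "x": a,
                "y": b,
                "method": "spearman",
                "estimate": res.rho,
                "p_value": res.p_value,
                "n": res.n,
                "jackknife": res.jackknife_estimate,
            }
        )
    fit = linear_fit(p["body_weight_kg"].to_numpy(), p["cancer_mortality_pct"].to_numpy())
    rows.append(
        {
            "x": "body_weight_kg",
            "y": "cancer_mortality_pct",
            "method": "linear_fit",
            "estimate": fit.r,
            "p_value": fit.p_value,
            "n": len(p),
            "jackknife": np.nan,
        }
    )
    return pd.DataFrame(rows)
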