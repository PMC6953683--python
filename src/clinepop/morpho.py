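"""Trait-environment regressions, allometric correction, and trait-space PCA.

Traits are per-individual morphological measurements (bill length/height,
wing chord, tail, tarsus in mm; body mass in g). Regressions against the
environmental gradient choose between a linear and a quadratic polynomial by
small-sample-corrected AIC; allometric correction regresses a trait on body
mass and passes the residuals downstream; the trait PCA works on the
correlation matrix so that traits measured in different units contribute
equally.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "TraitPca",
    "TRAIT_COLUMNS",
    "fit_trait_env",
    "allometric_residuals",
    "trait_pca",
]

TRAIT_COLUMNS = ("bill_length", "bill_height", "wing", "tail", "tarsus")


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    coefficients: dict[str, float]  # intercept, x, optionally x2
    p_value: float  # model F-test p
    r_squared: float
    degree: int
    n: int
    aicc: float


@dataclasses.dataclass
class TraitPca:
    loadings: pd.DataFrame  # traits x components
    variance_fractions: np.ndarray
    scores: pd.DataFrame  # samples x components
    n_dropped: int


def _aicc(model) -> float:
    k = model.df_model + 1 + 1  # coefficients + error variance
    n = model.nobs
    if n - k - 1 <= 0:
        return np.inf
    return model.aic + 2 * k * (k + 1) / (n - k - 1)


def fit_trait_env(
    trait: np.ndarray | pd.Series,
    env: np.ndarray | pd.Series,
    degree: int | str = "auto",
) -> RegressionFit:
    """Least-squares fit of a trait on an environmental value.

    ``degree`` may be 1, 2, or "auto" (pick by corrected AIC; the quadratic
    is only considered with >= 4 complete pairs). Reports the model F-test
    p-value and R^2.
    """
    trait = np.asarray(trait, dtype=float)
    env = np.asarray(env, dtype=float)
    ok = np.isfinite(trait) & np.isfinite(env)
    y, x = trait[ok], env[ok]
    if y.size < 3:
        raise ValueError("at least three paired observations are required")
    if np.std(x) == 0:
        raise ValueError("environment is constant")

    def fit_deg(d: int):
        X = sm.add_constant(np.column_stack([x**j for j in range(1, d + 1)]))
        return sm.OLS(y, X).fit()

    candidates = {1: fit_deg(1)}
    if (degree in (2, "auto")) and y.size >= 4:
        candidates[2] = fit_deg(2)
    if degree == "auto":
        chosen = min(candidates, key=lambda d: _aicc(candidates[d]))
    else:
        if degree not in candidates:
            raise ValueError(f"degree {degree} not fittable with n={y.size}")
        chosen = degree
    model = candidates[chosen]
    names = ["intercept", "x", "x2"][: chosen + 1]
    coefs = dict(zip(names, model.params))
    p = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else float("nan")
    return RegressionFit(
        coefficients=coefs,
        p_value=p,
        r_squared=float(model.rsquared),
        degree=chosen,
        n=int(y.size),
        aicc=_aicc(model),
    )


def allometric_residuals(
    trait: np.ndarray | pd.Series, mass: np.ndarray | pd.Series
) -> np.ndarray:
    """Residuals of the trait ~ body-mass regression (size correction).

    Returned array is aligned with the input (NaN where either value was
    missing); residuals have mean exactly zero and zero correlation with mass
    by construction.
    """
    trait = np.asarray(trait, dtype=float)
    mass = np.asarray(mass, dtype=float)
    ok = np.isfinite(trait) & np.isfinite(mass)
    if ok.sum() < 3:
        raise ValueError("at least three paired observations are required")
    if np.std(mass[ok]) == 0:
        raise ValueError("body mass is constant")
    X = sm.add_constant(mass[ok])
    res = sm.OLS(trait[ok], X).fit()
    out = np.full_like(trait, np.nan)
    out[ok] = res.resid
    return out


def trait_pca(
    table: pd.DataFrame,
    traits: tuple[str, ...] = TRAIT_COLUMNS,
) -> TraitPca:
    """PCA of the trait correlation matrix over complete cases.

    Traits are centered and unit-scaled, so variance fractions are eigenvalues
    of the correlation matrix divided by the trait count. Sign convention:
    within each component, the largest-magnitude loading is positive. Samples
    with any missing trait are dropped (count reported).
    """
    missing_cols = [t for t in traits if t not in table.columns]
    if missing_cols:
        raise KeyError(f"trait columns absent from the table: {missing_cols}")
    sub = table[list(traits)].astype(float)
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if len(complete) < 3:
        raise ValueError("at least three complete cases are required")
    zero_var = [t for t in traits if complete[t].std(ddof=0) == 0]
    if zero_var:
        raise ValueError(f"zero-variance trait(s): {zero_var}")

    Z = (complete - complete.mean()) / complete.std(ddof=0)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # sign convention: dominant loading positive
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    comp_names = [f"PC{j + 1}" for j in range(len(traits))]
    loadings = pd.DataFrame(eigvec, index=list(traits), columns=comp_names)
    scores = pd.DataFrame(
        Z.to_numpy() @ eigvec, index=complete.index, columns=comp_names
    )
    if "sample_id" in table.columns:
        scores.insert(0, "sample_id", table.loc[complete.index, "sample_id"])
    return TraitPca(
        loadings=loadings,
        variance_fractions=np.clip(eigval, 0, None) / len(traits),
        scores=scores,
        n_dropped=n_dropped,
    )
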