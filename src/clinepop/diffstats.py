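"""Weir-Cockerham F_ST and genotype PCA.

Implements the moment estimator of theta from the among-population (a),
among-individual-within-population (b) and within-individual (c) variance
components, computed from unphased dosage data (heterozygote = dosage 1) with
unequal sample sizes. Multilocus and pairwise estimates use the ratio of sums
of components; pairwise uncertainty comes from a nonparametric bootstrap over
loci.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from ._utils import child_rng
from .genio import GenotypeTable

__all__ = [
    "LocusFstComponents",
    "FstEstimate",
    "PairwiseFstMatrix",
    "wc_components_locus",
    "wc_components_table",
    "multilocus_theta",
    "global_fst",
    "pairwise_fst_bootstrap",
    "pca_genotypes",
]


@dataclasses.dataclass(frozen=True)
class LocusFstComponents:
    """Per-locus variance components; theta = a / (a + b + c), NaN if undefined."""

    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if not np.isfinite(denom) or denom == 0:
            return float("nan")
        return self.a / denom


@dataclasses.dataclass(frozen=True)
class FstEstimate:
    theta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int

    @property
    def ci_excludes_point(self) -> bool:
        """Percentile CIs at tiny locus counts can exclude the point estimate."""
        return not (self.ci_low <= self.theta <= self.ci_high)


@dataclasses.dataclass
class PairwiseFstMatrix:
    populations: list[str]
    theta: np.ndarray  # symmetric, zero diagonal
    estimates: dict[tuple[str, str], FstEstimate]

    @property
    def mean_offdiag(self) -> float:
        iu = np.triu_indices(len(self.populations), k=1)
        vals = self.theta[iu]
        return float(np.nanmean(vals)) if vals.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.populations, columns=self.populations)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def _wc_arrays(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized WC84 components.

    Parameters are (n_pops, n_loci) arrays of per-population sample sizes
    (called individuals), ALT-allele frequencies, and observed heterozygote
    proportions; entries with n == 0 are ignored locus-wise. Returns per-locus
    (a, b, c); loci with fewer than two sampled populations or with mean
    sample size <= 1 come out NaN.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    has = n > 0
    r = has.sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n.sum(axis=0)
        n_bar = n_sum / r
        n2_sum = (n * n).sum(axis=0)
        n_c = (n_sum - n2_sum / n_sum) / (r - 1.0)
        p_bar = np.nansum(np.where(has, n * p, 0.0), axis=0) / n_sum
        s2 = np.nansum(np.where(has, n * (p - p_bar) ** 2, 0.0), axis=0) / (
            (r - 1.0) * n_bar
        )
        h_bar = np.nansum(np.where(has, n * h, 0.0), axis=0) / n_sum
        pq = p_bar * (1.0 - p_bar)

        inner = pq - (r - 1.0) / r * s2 - h_bar / 4.0
        a = n_bar / n_c * (s2 - inner / (n_bar - 1.0))
        b = n_bar / (n_bar - 1.0) * (
            pq - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    bad = (r < 2) | (n_bar <= 1.0) | ~np.isfinite(n_c) | (n_c <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _pop_summaries(table: GenotypeTable):
    """(n, p, h) arrays of shape (n_pops, n_loci) plus the population order."""
    pops = list(table.pop_indices())
    n = np.zeros((len(pops), table.n_loci))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, (pop, idx) in enumerate(table.pop_indices().items()):
        d = table.dosages[idx]
        called = np.isfinite(d)
        nk = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            n[k] = nk
            p[k] = np.where(nk > 0, np.nansum(d, axis=0) / (2.0 * nk), np.nan)
            h[k] = np.where(nk > 0, (d == 1).sum(axis=0) / nk, np.nan)
    return n, p, h, pops


def wc_components_table(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (a, b, c) arrays for every locus of a table."""
    n, p, h, _ = _pop_summaries(table)
    return _wc_arrays(n, p, h)


def wc_components_locus(dosages_by_pop: list[np.ndarray]) -> LocusFstComponents:
    """WC84 components for a single locus given per-population dosage vectors.

    A locus observed in fewer than two populations yields NaN components (and
    hence an undefined theta) rather than raising.
    """
    cols = []
    for d in dosages_by_pop:
        d = np.asarray(d, dtype=float)
        called = np.isfinite(d)
        nk = float(called.sum())
        if nk > 0:
            cols.append(
                (nk, np.nansum(d) / (2.0 * nk), float((d == 1).sum() / nk))
            )
        else:
            cols.append((0.0, np.nan, np.nan))
    n = np.array([[c[0]] for c in cols])
    p = np.array([[c[1]] for c in cols])
    h = np.array([[c[2]] for c in cols])
    a, b, c = _wc_arrays(n, p, h)
    return LocusFstComponents(float(a[0]), float(b[0]), float(c[0]))


def multilocus_theta(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums multilocus theta, skipping loci with undefined components.

    Can be negative; monomorphic loci contribute zeros to both sums and are
    effectively neutral to the ratio.
    """
    a = np.asarray(a, dtype=float)
    denom = a + np.asarray(b, dtype=float) + np.asarray(c, dtype=float)
    ok = np.isfinite(a) & np.isfinite(denom)
    if not ok.any() or denom[ok].sum() == 0:
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


def global_fst(table: GenotypeTable) -> float:
    """Multilocus theta across all populations of a table."""
    return multilocus_theta(*wc_components_table(table))


# ---------------------------------------------------------------------------
# pairwise bootstrap
# ---------------------------------------------------------------------------

def _bootstrap_theta(
    a: np.ndarray, abc: np.ndarray, n_boot: int, rng: np.random.Generator,
    chunk: int = 512,
) -> np.ndarray:
    """Bootstrap multilocus theta by resampling loci with replacement.

    Implemented with multinomial locus weights so each replicate is a weighted
    ratio of sums; chunked to bound memory.
    """
    ok = np.isfinite(a) & np.isfinite(abc)
    a, abc = a[ok], abc[ok]
    L = a.size
    if L == 0:
        return np.full(n_boot, np.nan)
    out = np.empty(n_boot)
    w_p = np.full(L, 1.0 / L)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        w = rng.multinomial(L, w_p, size=m).astype(float)
        num = w @ a
        den = w @ abc
        with np.errstate(invalid="ignore", divide="ignore"):
            out[done : done + m] = np.where(den != 0, num / den, np.nan)
        done += m
    return out


def pairwise_fst_bootstrap(
    table: GenotypeTable,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    two_sided: bool = False,
) -> PairwiseFstMatrix:
    """Pairwise multilocus theta with bootstrap CIs and p-values.

    Each pair is estimated on that pair's samples only. The bootstrap
    resamples loci with replacement; the CI is the percentile interval and the
    p-value the bootstrap tail at zero (one-sided against theta > 0 by
    default; ``two_sided`` doubles the smaller tail).
    """
    rng = child_rng(seed, "pairwise_fst")
    pops = [p for p, idx in table.pop_indices().items() if len(idx) > 0]
    dropped = [p for p, idx in table.pop_indices().items() if len(idx) == 0]
    if dropped:
        warnings.warn(f"populations without samples excluded: {dropped}")
    if len(pops) < 2:
        raise ValueError("at least two populations with samples are required")

    alpha = (1.0 - level) / 2.0
    k = len(pops)
    theta = np.zeros((k, k))
    estimates: dict[tuple[str, str], FstEstimate] = {}
    idx_of = table.pop_indices()
    for i in range(k):
        for j in range(i + 1, k):
            rows = np.concatenate([idx_of[pops[i]], idx_of[pops[j]]])
            sub = table.take_samples(rows)
            a, b, c = wc_components_table(sub)
            t = multilocus_theta(a, b, c)
            boot = _bootstrap_theta(a, a + b + c, n_boot, rng)
            boot_ok = boot[np.isfinite(boot)]
            if boot_ok.size:
                lo, hi = np.percentile(boot_ok, [100 * alpha, 100 * (1 - alpha)])
                p_low = float((boot_ok <= 0).mean())
                p = min(1.0, 2 * min(p_low, 1 - p_low)) if two_sided else p_low
            else:
                lo = hi = p = float("nan")
            est = FstEstimate(t, float(lo), float(hi), p, n_boot)
            estimates[(pops[i], pops[j])] = est
            theta[i, j] = theta[j, i] = t
    return PairwiseFstMatrix(pops, theta, estimates)


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------

def pca_genotypes(
    table: GenotypeTable,
    n_components: int = 10,
    scale: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the dosage matrix.

    Loci are centered at twice their ALT frequency; missing calls are imputed
    to the locus mean (i.e. zero after centering); ``scale`` divides by the
    binomial SD sqrt(p(1-p)). All-missing loci are dropped with a warning.
    Returns (scores, variance_fractions); scores have one row per sample.
    """
    if table.n_samples < 2 or table.n_loci < 2:
        raise ValueError("PCA needs at least 2 samples and 2 loci")
    X = table.dosages.copy()
    all_missing = np.all(np.isnan(X), axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing loci")
        X = X[:, ~all_missing]
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X) - mu
    if scale:
        p = mu / 2.0
        sd = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
        X = X / sd
    n_components = min(n_components, table.n_samples - 1, X.shape[1])
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    total = (X**2).sum()
    frac = (s**2 / total)[:n_components] if total > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * s[:n_components]
    return scores, frac
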