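"""Selection scans and gene-window annotation.

Three complementary scans:

* :func:`outflank_scan` — fits a trimmed scaled chi-square envelope to the
  distribution of per-locus F_ST over putatively neutral loci and flags loci
  in the right tail (Benjamini-Hochberg q < 0.05 by default). The likelihood
  uses per-locus F_ST without the finite-sample correction (which is never
  negative); reported per-locus values also include the corrected theta.
* :func:`rda_scan` — redundancy analysis of the dosage matrix on standardized
  environmental predictors; loci whose scores on any of the first constrained
  axes fall more than 3 SD from the axis mean are flagged and assigned the
  predictor best correlated with their population allele frequencies.
* :func:`latent_factor_assoc` — per-locus linear association between dosage
  and a predictor with the top-K genotype principal components as covariates.
  This is a least-squares structure-corrected association scan, not an MCMC
  latent-factor mixed model; outputs are labeled accordingly.

Gene annotation reports every gene within a +/-25 kb window of a candidate
SNP, given a GFF3 annotation on the same coordinate system.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._utils import bh_qvalues
from .diffstats import _pop_summaries, _wc_arrays, multilocus_theta
from .genio import GenotypeTable

__all__ = [
    "NeutralEnvelopeFit",
    "OutlierScanResult",
    "RdaScanResult",
    "AssocScanResult",
    "GeneWindowHit",
    "outflank_scan",
    "rda_scan",
    "latent_factor_assoc",
    "read_gff3_genes",
    "genes_within_window",
    "allele_freq_by_population",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class NeutralEnvelopeFit:
    """Fitted neutral F_ST envelope (scaled chi-square on uncorrected F_ST)."""

    mean_fst: float  # neutral mean on the corrected (theta) scale
    mean_fst_nocorr: float  # fitted mean of the uncorrected distribution
    df: float
    trim_low: float
    trim_high: float
    h_min: float
    n_used: int


@dataclasses.dataclass
class OutlierScanResult:
    table: pd.DataFrame  # locus_id, fst, fst_uncorrected, he, p_right, q, outlier

    @property
    def outlier_ids(self) -> list[str]:
        return self.table.loc[self.table["outlier"], "locus_id"].tolist()


@dataclasses.dataclass
class RdaScanResult:
    scores: pd.DataFrame  # locus_id + one column per constrained axis
    axis_variance: np.ndarray
    outliers: pd.DataFrame  # locus_id, axis, score, best_predictor, r

    @property
    def outlier_ids(self) -> list[str]:
        return self.outliers["locus_id"].unique().tolist()


@dataclasses.dataclass
class AssocScanResult:
    table: pd.DataFrame  # locus_id, slope, t, p, q
    k: int
    gif: float = 1.0  # genomic inflation factor used to calibrate p-values

    @property
    def outlier_ids(self) -> list[str]:
        return self.table.loc[self.table["q"] < 0.05, "locus_id"].tolist()


@dataclasses.dataclass(frozen=True)
class GeneWindowHit:
    locus_id: str
    gene_id: str
    distance: int  # bp; 0 when the SNP lies inside the gene
    direction: str  # "upstream" | "downstream" | "within"


# ---------------------------------------------------------------------------
# trimmed chi-square F_ST scan
# ---------------------------------------------------------------------------

def _uncorrected_fst(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus uncorrected F_ST and expected heterozygosity.

    The uncorrected statistic is the infinite-sample limit of the WC ratio,
    s^2 / (p(1-p) + s^2/r): non-negative, so a scaled chi-square can be fitted
    to it directly.
    """
    n, p, h, _ = _pop_summaries(table)
    has = n > 0
    r = has.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n.sum(axis=0)
        n_bar = n_sum / r
        p_bar = np.nansum(np.where(has, n * p, 0.0), axis=0) / n_sum
        s2 = np.nansum(np.where(has, n * (p - p_bar) ** 2, 0.0), axis=0) / (
            (r - 1.0) * n_bar
        )
        pq = p_bar * (1.0 - p_bar)
        fst_nc = np.where(pq + s2 / r > 0, s2 / (pq + s2 / r), np.nan)
    fst_nc[r < 2] = np.nan
    he = 2.0 * p_bar * (1.0 - p_bar)
    return fst_nc, he


def _fit_trimmed_chi2(
    values: np.ndarray, trim_low: float, trim_high: float, df0: float
) -> tuple[float, float]:
    """ML fit of mean and df of a scaled chi-square to a two-sided-trimmed sample.

    values must be sorted ascending and positive. Returns (mean, df).
    """
    n = values.size
    lo = int(np.floor(trim_low * n))
    hi = n - int(np.floor(trim_high * n))
    core = values[lo:hi]
    L, U = core[0], core[-1]

    def nll(theta: np.ndarray) -> float:
        log_m, log_df = theta
        m, df = np.exp(log_m), np.exp(log_df)
        shape, scl = df / 2.0, 2.0 * m / df
        logpdf = stats.gamma.logpdf(core, shape, scale=scl)
        z = stats.gamma.cdf(U, shape, scale=scl) - stats.gamma.cdf(
            L, shape, scale=scl
        )
        if z <= 0 or not np.isfinite(z):
            return 1e12
        return float(-(logpdf.sum() - core.size * np.log(z)))

    x0 = np.array([np.log(core.mean()), np.log(df0)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000})
    m, df = np.exp(res.x)
    return float(m), float(df)


def outflank_scan(
    table: GenotypeTable,
    trim_low: float = 0.05,
    trim_high: float = 0.05,
    h_min: float = 0.1,
    q_threshold: float = 0.05,
) -> tuple[NeutralEnvelopeFit, OutlierScanResult]:
    """Trimmed chi-square F_ST outlier scan.

    Fits the neutral envelope on uncorrected per-locus F_ST values with
    expected heterozygosity >= ``h_min``, after trimming both tails, then
    assigns a right-tail p-value to every locus (including those excluded
    from the fit) and flags loci at BH q < ``q_threshold``.
    """
    if not (0 <= trim_low < 0.5 and 0 <= trim_high < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    pops = table.pop_indices()
    if len(pops) < 2:
        raise ValueError("outlier scan requires at least two populations")

    fst_nc, he = _uncorrected_fst(table)
    a, b, c = _wc_arrays(*_pop_summaries(table)[:3])
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(a + b + c != 0, a / (a + b + c), np.nan)

    informative = np.isfinite(fst_nc) & (fst_nc > 0)
    fit_mask = informative & (he >= h_min)
    n_fit = int(fit_mask.sum())
    if n_fit < 2:
        raise ValueError("too few informative loci to fit the neutral envelope")
    if n_fit < 50:
        warnings.warn(
            f"only {n_fit} loci enter the envelope fit; estimates will be unstable"
        )
    vals = np.sort(fst_nc[fit_mask])
    if np.allclose(vals, vals[0]):
        raise ValueError(
            "degenerate fit: all per-locus F_ST values are identical"
        )
    df0 = max(len(pops) - 1.0, 1.0)
    mean_nc, df = _fit_trimmed_chi2(vals, trim_low, trim_high, df0)

    # corrected-scale neutral mean: ratio of sums over the fit set
    mean_corr = multilocus_theta(a[fit_mask], b[fit_mask], c[fit_mask])

    shape, scl = df / 2.0, 2.0 * mean_nc / df
    p_right = np.full(table.n_loci, np.nan)
    p_right[informative] = stats.gamma.sf(fst_nc[informative], shape, scale=scl)
    q = bh_qvalues(p_right)
    out = pd.DataFrame(
        {
            "locus_id": table.loci["locus_id"],
            "fst": theta,
            "fst_uncorrected": fst_nc,
            "he": he,
            "in_fit": fit_mask,
            "p_right": p_right,
            "q": q,
            "outlier": q < q_threshold,
        }
    )
    fit = NeutralEnvelopeFit(
        mean_fst=float(mean_corr),
        mean_fst_nocorr=mean_nc,
        df=df,
        trim_low=trim_low,
        trim_high=trim_high,
        h_min=h_min,
        n_used=n_fit,
    )
    return fit, OutlierScanResult(out)


# ---------------------------------------------------------------------------
# redundancy analysis scan
# ---------------------------------------------------------------------------

def _impute_center(dosages: np.ndarray) -> np.ndarray:
    mu = np.nanmean(dosages, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    return np.where(np.isnan(dosages), mu, dosages) - mu


def rda_scan(
    table: GenotypeTable,
    env: pd.DataFrame,
    n_axes: int = 3,
    sd_mult: float = 3.0,
) -> RdaScanResult:
    """Redundancy-analysis outlier scan.

    ``env`` is a per-population predictor table indexed (or keyed by a
    ``population`` column) by population id; each sample inherits its
    population's predictor values. Dosages are mean-imputed, centered and
    scaled to unit variance per locus (so rare and common loci weigh the
    same), predictors z-scored; the constrained axes are the principal axes of the
    fitted values of the multivariate regression of dosages on predictors.
    A locus is an outlier when its loading on any retained axis lies more
    than ``sd_mult`` SDs from that axis's mean; each outlier is assigned the
    predictor with the largest |Pearson r| against its population allele
    frequencies.
    """
    if "population" in env.columns:
        env = env.set_index("population")
    env = env.select_dtypes("number")
    pops = list(table.pop_indices())
    missing = [p for p in pops if p not in env.index]
    if missing:
        raise ValueError(f"populations missing from the predictor table: {missing}")
    pred_names = list(env.columns)
    if not pred_names:
        raise ValueError("no numeric predictors supplied")
    P = env.loc[pops, pred_names].to_numpy(dtype=float)
    if np.any(P.std(axis=0) == 0):
        const = [pred_names[i] for i in np.flatnonzero(P.std(axis=0) == 0)]
        raise ValueError(f"constant predictor(s): {const}")
    if n_axes > len(pred_names):
        warnings.warn(
            f"n_axes={n_axes} exceeds the {len(pred_names)} predictors; clipping"
        )
        n_axes = len(pred_names)

    # per-sample design
    pop_of = {p: k for k, p in enumerate(pops)}
    rows = np.array([pop_of[p] for p in table.pop_labels])
    X = P[rows]
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    Y = _impute_center(table.dosages)
    # unit-variance loci keep MAF heterogeneity out of the loading tails,
    # so the 3-SD outlier rule is calibrated across the frequency spectrum
    sd = Y.std(axis=0)
    sd[sd == 0] = 1.0
    Y = Y / sd

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Yhat = X @ beta
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = min(n_axes, int((s > 1e-10).sum()))
    total_inertia = float((Y**2).sum())
    axis_var = s[:n_axes] ** 2 / total_inertia if total_inertia > 0 else s[:n_axes] * 0

    scores = (Vt[:n_axes].T * s[:n_axes])  # loadings scaled by axis importance
    score_df = pd.DataFrame(
        scores, columns=[f"RDA{k + 1}" for k in range(n_axes)]
    )
    score_df.insert(0, "locus_id", table.loci["locus_id"].to_numpy())

    # per-population allele frequencies for predictor assignment
    _, pfreq, _, _ = _pop_summaries(table)
    out_rows = []
    for k in range(n_axes):
        col = scores[:, k]
        mu, sd = col.mean(), col.std()
        if sd == 0:
            continue
        flagged = np.flatnonzero(np.abs(col - mu) > sd_mult * sd)
        for j in flagged:
            freq = pfreq[:, j]
            ok = np.isfinite(freq)
            best, best_r = None, 0.0
            for m, name in enumerate(pred_names):
                if ok.sum() >= 3 and np.std(freq[ok]) > 0:
                    r = np.corrcoef(freq[ok], P[ok, m])[0, 1]
                else:
                    r = np.nan
                if np.isfinite(r) and abs(r) >= abs(best_r):
                    best, best_r = name, r
            out_rows.append(
                (
                    table.loci["locus_id"].iloc[j],
                    f"RDA{k + 1}",
                    float(col[j]),
                    best,
                    float(best_r),
                )
            )
    outliers = pd.DataFrame(
        out_rows, columns=["locus_id", "axis", "score", "best_predictor", "r"]
    )
    return RdaScanResult(score_df, axis_var, outliers)


# ---------------------------------------------------------------------------
# latent-factor association scan
# ---------------------------------------------------------------------------

def latent_factor_assoc(
    table: GenotypeTable,
    predictor: np.ndarray | pd.Series,
    k: int = 1,
    calibrate: bool = True,
) -> AssocScanResult:
    """Structure-corrected least-squares association scan.

    Regresses each locus's (mean-imputed) dosage on the predictor plus
    ``k`` latent structure factors; reports the two-sided p-value for the
    predictor slope and BH q-values. The factors are the top-k principal
    axes of the dosage matrix after the predictor has been regressed out —
    estimating structure net of the tested effect, as latent-factor
    association models do; naive PCA factors would absorb a strong cline and
    erase the very signal being tested. With ``k = 0`` this reduces to an
    ordinary per-locus regression. ``calibrate`` rescales the squared
    statistics by the genomic inflation factor (median chi-square rule)
    before converting to p-values. Least-squares stand-in for an MCMC
    latent-factor model; do not report as LFMM.
    """
    x = np.asarray(predictor, dtype=float)
    if x.shape != (table.n_samples,):
        raise ValueError("predictor must have one value per sample")
    if not np.isfinite(x).all():
        raise ValueError("predictor contains missing values")
    if k < 0 or k >= table.n_samples - 2:
        raise ValueError("k must satisfy 0 <= k < n_samples - 2")

    Y = _impute_center(table.dosages)
    cols = [np.ones(table.n_samples), (x - x.mean()) / (x.std() or 1.0)]
    if k > 0:
        Xp = np.column_stack(cols)
        resid = Y - Xp @ (np.linalg.pinv(Xp) @ Y)
        U, s, _ = np.linalg.svd(resid, full_matrices=False)
        factors = U[:, :k] * s[:k]
        cols.extend(factors[:, i] for i in range(factors.shape[1]))
    X = np.column_stack(cols)
    n, p_dim = X.shape
    dof = n - p_dim
    if dof < 1:
        raise ValueError("not enough samples for the requested number of factors")

    XtX_inv = np.linalg.pinv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # (p_dim, n_loci)
    resid = Y - X @ B
    s2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.clip(s2 * XtX_inv[1, 1], 1e-300, None))
    slope = B[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = slope / se
    # monomorphic loci carry no signal; give them p = 1 rather than 0/0 noise
    mono = np.nanstd(Y, axis=0) == 0
    gif = 1.0
    if calibrate:
        # genomic-control calibration: few-population designs leave residual
        # drift variance along the predictor that the orthogonal factors
        # cannot absorb, inflating the statistics genome-wide
        z2 = t[~mono] ** 2
        if z2.size:
            gif = max(float(np.median(z2)) / stats.chi2.median(1), 1e-8)
        pvals = stats.chi2.sf(t**2 / gif, 1)
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals[mono] = 1.0
    q = bh_qvalues(pvals)
    tab = pd.DataFrame(
        {
            "locus_id": table.loci["locus_id"],
            "slope": slope,
            "t": t,
            "p": pvals,
            "q": q,
        }
    )
    return AssocScanResult(tab, k, gif=gif)


# ---------------------------------------------------------------------------
# gene windows
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene features of a GFF3 file as (gene_id, scaffold, start, end).

    1-based inclusive coordinates, as in GFF3. Only ``gene`` features are
    kept; the gene id is taken from the ``ID`` or ``Name`` attribute.
    """
    from gffutils.iterators import DataIterator

    rows = []
    for feat in DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gid = feat.attributes.get("ID", feat.attributes.get("Name", ["?"]))[0]
        rows.append((gid, feat.seqid, int(feat.start), int(feat.end)))
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end"])


def genes_within_window(
    loci: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 25_000,
) -> list[GeneWindowHit]:
    """Every gene whose interval intersects [pos - window, pos + window].

    ``loci`` needs columns locus_id, scaffold, position; ``genes`` the columns
    of :func:`read_gff3_genes`. Distance is 0 (direction "within") when the
    SNP lies inside the gene; otherwise the gap to the nearest gene edge,
    with direction naming the side of the SNP the gene falls on (upstream =
    lower coordinate). Loci on scaffolds absent from the annotation yield no
    hits (logged).
    """
    hits: list[GeneWindowHit] = []
    by_scaffold = {s: g for s, g in genes.groupby("scaffold")}
    for locus in loci.itertuples(index=False):
        g = by_scaffold.get(locus.scaffold)
        if g is None:
            logger.info("scaffold %s absent from annotation", locus.scaffold)
            continue
        pos = int(locus.position)
        near = g[(g["end"] >= pos - window) & (g["start"] <= pos + window)]
        for gene in near.itertuples(index=False):
            if gene.start <= pos <= gene.end:
                hits.append(GeneWindowHit(locus.locus_id, gene.gene_id, 0, "within"))
            elif gene.end < pos:
                hits.append(
                    GeneWindowHit(
                        locus.locus_id, gene.gene_id, pos - gene.end, "upstream"
                    )
                )
            else:
                hits.append(
                    GeneWindowHit(
                        locus.locus_id, gene.gene_id, gene.start - pos, "downstream"
                    )
                )
    return hits


def allele_freq_by_population(
    table: GenotypeTable,
    locus_ids: list[str] | None = None,
    min_n: int = 5,
    strict_greater: bool = False,
    gene_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """ALT-allele frequencies per population for a set of loci.

    Populations with fewer than ``min_n`` genotyped individuals (strictly
    more than ``min_n`` required when ``strict_greater``) are excluded. When
    ``gene_of`` maps locus ids to gene ids, frequencies of loci linked to the
    same gene are averaged into one row per gene.
    """
    if locus_ids is None:
        locus_ids = table.loci["locus_id"].tolist()
    col_of = {l: j for j, l in enumerate(table.loci["locus_id"])}
    bad = [l for l in locus_ids if l not in col_of]
    if bad:
        raise KeyError(f"unknown locus ids: {bad[:5]}")
    cols = [col_of[l] for l in locus_ids]

    keep_pops = []
    freqs = []
    for pop, idx in table.pop_indices().items():
        n = len(idx)
        ok = n > min_n if strict_greater else n >= min_n
        if not ok:
            continue
        keep_pops.append(pop)
        d = table.dosages[np.ix_(idx, cols)]
        with np.errstate(invalid="ignore"):
            freqs.append(np.nanmean(d, axis=0) / 2.0)
    out = pd.DataFrame(
        np.array(freqs) if freqs else np.empty((0, len(cols))),
        index=keep_pops,
        columns=locus_ids,
    )
    out.index.name = "population"
    if gene_of is not None:
        out = out.T.groupby([gene_of.get(l, l) for l in out.columns]).mean().T
        out.columns.name = "gene_id"
    return out
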