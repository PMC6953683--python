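"""Geographic/environmental distance matrices and multiple matrix regression.

Isolation by distance (IBD) and by environment (IBE) are tested by regressing
a genetic distance matrix on geographic and environmental distance matrices,
with significance from joint row/column permutation of the response matrix
(node permutation — the standard null for regression on distance matrices).

Geographic distances: great-circle (haversine) in km, and "coastal" distance —
the absolute difference in along-path arclength after projecting each site
onto a coastline polyline — for species whose dispersal follows the shore.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._utils import child_rng

__all__ = [
    "DistanceMatrix",
    "MmrrResult",
    "haversine_km",
    "build_distances",
    "mmrr",
]

_EARTH_RADIUS_KM = 6371.0088


@dataclasses.dataclass
class DistanceMatrix:
    populations: list[str]
    values: np.ndarray
    kind: str  # geo-euclidean | coastal | environmental | genetic

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.populations)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match population count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")

    def lower_triangle(self) -> np.ndarray:
        il = np.tril_indices(len(self.populations), k=-1)
        return self.values[il]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.populations, columns=self.populations
        )


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _project_to_polyline(
    lat: float, lon: float, line: np.ndarray, cumlen: np.ndarray
) -> tuple[float, float]:
    """Arclength (km) of the closest polyline point and the snap distance (km).

    The projection is done per segment in a local equirectangular frame, which
    is accurate at the tens-of-km scale of coastal sampling.
    """
    lat0 = np.radians(lat)
    kx = _EARTH_RADIUS_KM * np.cos(lat0) * np.pi / 180.0
    ky = _EARTH_RADIUS_KM * np.pi / 180.0
    px, py = lon * kx, lat * ky
    ax, ay = line[:-1, 0] * kx, line[:-1, 1] * ky
    bx, by = line[1:, 0] * kx, line[1:, 1] * ky
    dx, dy = bx - ax, by - ay
    seg2 = dx * dx + dy * dy
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(seg2 > 0, ((px - ax) * dx + (py - ay) * dy) / seg2, 0.0)
    t = np.clip(t, 0.0, 1.0)
    cx, cy = ax + t * dx, ay + t * dy
    d2 = (px - cx) ** 2 + (py - cy) ** 2
    k = int(np.argmin(d2))
    seglen = cumlen[k + 1] - cumlen[k]
    return float(cumlen[k] + t[k] * seglen), float(np.sqrt(d2[k]))


def build_distances(
    sites: pd.DataFrame,
    coastline: pd.DataFrame | None = None,
    env_columns: tuple[str, ...] = ("bio12",),
    snap_tol_km: float = 100.0,
) -> dict[str, DistanceMatrix]:
    """Geographic and environmental distance matrices from a site table.

    ``sites`` needs columns population, lon, lat plus the requested
    environmental columns; ``coastline`` is an ordered polyline TSV-style
    frame with lon/lat columns. Returns a dict keyed ``geo-euclidean``,
    ``env:<column>`` and (when a coastline is given) ``coastal``. A site
    farther than ``snap_tol_km`` from the coastline raises.
    """
    if len(sites) < 2:
        raise ValueError("at least two sites are required")
    if sites["lat"].abs().max() > 90 or sites["lon"].abs().max() > 180:
        raise ValueError("coordinates out of range")
    pops = sites["population"].astype(str).tolist()
    lat = sites["lat"].to_numpy(dtype=float)
    lon = sites["lon"].to_numpy(dtype=float)
    out: dict[str, DistanceMatrix] = {}

    geo = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(geo, 0.0)
    out["geo-euclidean"] = DistanceMatrix(pops, geo, "geo-euclidean")

    for col in env_columns:
        v = sites[col].to_numpy(dtype=float)
        out[f"env:{col}"] = DistanceMatrix(
            pops, np.abs(v[:, None] - v[None, :]), "environmental"
        )

    if coastline is not None:
        line = coastline[["lon", "lat"]].to_numpy(dtype=float)
        if len(line) < 2:
            raise ValueError("coastline polyline needs at least two vertices")
        seg = haversine_km(line[:-1, 1], line[:-1, 0], line[1:, 1], line[1:, 0])
        cumlen = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.empty(len(pops))
        for i, pop in enumerate(pops):
            s[i], snap = _project_to_polyline(lat[i], lon[i], line, cumlen)
            if snap > snap_tol_km:
                raise ValueError(
                    f"site {pop} lies {snap:.1f} km from the coastline "
                    f"(tolerance {snap_tol_km} km)"
                )
        coast = np.abs(s[:, None] - s[None, :])
        np.fill_diagonal(coast, 0.0)
        out["coastal"] = DistanceMatrix(pops, coast, "coastal")
    return out


# ---------------------------------------------------------------------------
# multiple matrix regression with permutation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MmrrResult:
    predictors: list[str]
    coefficients: np.ndarray  # standardized betas, no intercept
    t_stats: np.ndarray
    t_pvalues: np.ndarray
    r_squared: float
    f_stat: float
    f_pvalue: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "beta": self.coefficients,
                "t": self.t_stats,
                "p": self.t_pvalues,
            }
        )


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("constant distance matrix cannot be scaled")
    return (v - v.mean()) / sd


def mmrr(
    response: DistanceMatrix,
    predictors: dict[str, DistanceMatrix] | list[DistanceMatrix],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> MmrrResult:
    """Multiple regression on distance matrices with permutation significance.

    Lower-triangle entries of every matrix are z-scored (diagonal excluded),
    then regressed by OLS. The null distribution jointly permutes rows and
    columns of the response matrix; p-values use the add-one rule
    (1 + #{perm >= obs}) / (1 + n_perm) for |t| and for F.
    """
    if isinstance(predictors, list):
        predictors = {m.kind or f"X{i}": m for i, m in enumerate(predictors)}
    names = list(predictors)
    k = len(response.populations)
    if k < 4:
        raise ValueError("at least four populations are required")
    for name, m in predictors.items():
        if m.populations != response.populations:
            raise ValueError(
                f"predictor '{name}' has different populations or order"
            )

    il = np.tril_indices(k, k=-1)
    y = _zscore(response.values[il])
    X = np.column_stack([_zscore(m.values[il]) for m in predictors.values()])
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("predictor matrices are collinear (rank-deficient design)")

    XtX_inv = np.linalg.inv(design.T @ design)
    hat = XtX_inv @ design.T

    def fit(yv: np.ndarray):
        beta = hat @ yv
        resid = yv - design @ beta
        sse = float(resid @ resid)
        sst = float(((yv - yv.mean()) ** 2).sum())
        dof = n - p - 1
        s2 = sse / dof
        se = np.sqrt(np.clip(s2 * np.diag(XtX_inv), 1e-300, None))
        t = beta / se
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        f = (r2 / p) / ((1.0 - r2) / dof) if r2 < 1.0 else np.inf
        return beta[1:], t[1:], r2, f

    beta_obs, t_obs, r2_obs, f_obs = fit(y)

    rng = child_rng(seed, "mmrr")
    t_ge = np.zeros(p)
    f_ge = 0
    vals = response.values
    for _ in range(n_perm):
        perm = rng.permutation(k)
        yp = _zscore(vals[np.ix_(perm, perm)][il])
        _, t_p, _, f_p = fit(yp)
        t_ge += np.abs(t_p) >= np.abs(t_obs) - 1e-12
        f_ge += f_p >= f_obs - 1e-12
    t_pvals = (1.0 + t_ge) / (1.0 + n_perm)
    f_pval = (1.0 + f_ge) / (1.0 + n_perm)
    return MmrrResult(
        predictors=names,
        coefficients=beta_obs,
        t_stats=t_obs,
        t_pvalues=t_pvals,
        r_squared=r2_obs,
        f_stat=f_obs,
        f_pvalue=float(f_pval),
        n_perm=n_perm,
    )
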