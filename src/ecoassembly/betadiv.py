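"""Beta-diversity statistics: distances, ordination, and permutation tests.

Bray-Curtis (optionally on Hellinger-transformed proportions), classical
PCoA, one-factor PERMANOVA and ANOSIM, great-circle distances, Mantel tests,
distance-decay regression, and Spearman environment correlations. All
permutation tests take an explicit seed and use the add-one convention
p = (1 + exceedances) / (1 + n_perm), so p is never exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from .errors import InvalidArgumentError

__all__ = [
    "bray_curtis",
    "pcoa",
    "OrdinationResult",
    "permanova",
    "anosim",
    "haversine_km",
    "haversine_matrix",
    "distance_decay",
    "mantel",
    "env_correlations",
]

EARTH_RADIUS_KM = 6371.0088


def bray_curtis(counts: pd.DataFrame, hellinger: bool = True) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    With ``hellinger`` (the default, matching standard preprocessing for
    community ordination) each sample is first transformed to the square
    root of its relative abundances.
    """
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero) > 0:
        raise InvalidArgumentError(f"all-zero sample(s): {list(zero)}")
    mat = (counts / totals).to_numpy(dtype=float)
    if hellinger:
        mat = np.sqrt(mat)
    d = squareform(pdist(mat.T, metric="braycurtis"))
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


@dataclass
class OrdinationResult:
    """Classical-scaling coordinates with the full eigenvalue spectrum."""

    coordinates: pd.DataFrame  # samples x axes, positive eigenvalues only
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dist: pd.DataFrame) -> OrdinationResult:
    """Principal-coordinate analysis (Gower's classical scaling).

    Eigendecomposition of the double-centered squared-distance matrix;
    negative eigenvalues are retained in the spectrum but contribute no
    coordinate axes.
    """
    n = dist.shape[0]
    if n < 3:
        raise InvalidArgumentError("PCoA needs at least 3 samples")
    d2 = np.asarray(dist, dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    prop = evals[pos] / evals[pos].sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.index, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


def _check_groups(dist: pd.DataFrame, groups) -> np.ndarray:
    g = np.asarray(pd.Series(groups, index=dist.index) if not isinstance(groups, pd.Series) else groups.loc[dist.index])
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2]
        raise InvalidArgumentError(f"singleton group(s): {list(small)}")
    return g


def _permanova_f(d2: np.ndarray, g: np.ndarray) -> float:
    n = len(g)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for lab in np.unique(g):
        idx = np.flatnonzero(g == lab)
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(np.unique(g))
    ssa = sst - ssw
    if ssw == 0:  # perfect within-group identity
        return np.inf
    return (ssa / (a - 1)) / (ssw / (n - a))


def permanova(
    dist: pd.DataFrame, groups, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """One-factor PERMANOVA pseudo-F with a label-permutation p-value."""
    g = _check_groups(dist, groups)
    d2 = np.asarray(dist, dtype=float) ** 2
    f_obs = _permanova_f(d2, g)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += _permanova_f(d2, rng.permutation(g)) >= f_obs
    return float(f_obs), (1.0 + exceed) / (1.0 + n_perm)


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / (n * (n - 1) / 4.0)


def anosim(
    dist: pd.DataFrame, groups, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """ANOSIM R statistic (rank-based) with a permutation p-value."""
    g = _check_groups(dist, groups)
    n = len(g)
    iu = np.triu_indices(n, 1)
    vec = np.asarray(dist, dtype=float)[iu]
    ranks = rankdata(vec)
    r_obs = _anosim_r(ranks, (g[iu[0]] == g[iu[1]]), n)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        gp = rng.permutation(g)
        exceed += _anosim_r(ranks, (gp[iu[0]] == gp[iu[1]]), n) >= r_obs
    return float(r_obs), (1.0 + exceed) / (1.0 + n_perm)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (WGS84 mean Earth radius 6371.0088 km)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def haversine_matrix(latitudes, longitudes, ids=None) -> pd.DataFrame:
    """Pairwise great-circle distances (km) between sample coordinates."""
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    if (np.abs(lat) > 90).any():
        raise InvalidArgumentError("latitude out of [-90, 90]")
    if (np.abs(lon) > 180).any():
        raise InvalidArgumentError("longitude out of [-180, 180]")
    n = len(lat)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    if ids is None:
        ids = [f"S{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(out, index=ids, columns=ids)


def _mantel_stat(v1: np.ndarray, v2: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(spearmanr(v1, v2).statistic)
    if method == "pearson":
        return float(np.corrcoef(v1, v2)[0, 1])
    raise InvalidArgumentError(f"unknown method {method!r}")


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    p-value is two-sided (|r_perm| >= |r_obs|) by permuting the sample ids of
    the second matrix.
    """
    if list(d1.index) != list(d2.index):
        raise InvalidArgumentError("distance matrices must share identical ids")
    n = d1.shape[0]
    iu = np.triu_indices(n, 1)
    m1 = np.asarray(d1, dtype=float)
    m2 = np.asarray(d2, dtype=float)
    r_obs = _mantel_stat(m1[iu], m2[iu], method)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        exceed += abs(_mantel_stat(m1[iu], m2[np.ix_(p, p)][iu], method)) >= abs(r_obs)
    return r_obs, (1.0 + exceed) / (1.0 + n_perm)


def distance_decay(
    counts: pd.DataFrame,
    latitudes,
    longitudes,
    hellinger: bool = True,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Distance-decay of community similarity with geographic distance.

    Similarity = 1 - Bray-Curtis; returns (Pearson r, Mantel-permutation
    two-sided p, least-squares slope per km) over all unordered sample pairs.
    """
    n = counts.shape[1]
    if n * (n - 1) // 2 < 10:
        raise InvalidArgumentError("need at least 10 sample pairs")
    sim = 1.0 - bray_curtis(counts, hellinger=hellinger)
    geo = haversine_matrix(latitudes, longitudes, ids=list(counts.columns))
    iu = np.triu_indices(n, 1)
    x = np.asarray(geo, dtype=float)[iu]
    y = np.asarray(sim, dtype=float)[iu]
    if np.ptp(x) == 0:
        raise InvalidArgumentError("all samples are co-located; slope undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.polyfit(x, y, 1)[0])
    rng = np.random.default_rng(seed)
    gm = np.asarray(geo, dtype=float)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_p = np.corrcoef(gm[np.ix_(p, p)][iu], y)[0, 1]
        exceed += abs(r_p) >= abs(r_obs)
    return r_obs, (1.0 + exceed) / (1.0 + n_perm), slope


def _spearman_perm_p(x: np.ndarray, y: np.ndarray, rho: float, seed: int) -> float:
    rng = np.random.default_rng(seed)
    n_perm = 9999
    exceed = 0
    for _ in range(n_perm):
        r = spearmanr(x, rng.permutation(y)).statistic
        exceed += abs(r) >= abs(rho) - 1e-12
    return (1.0 + exceed) / (1.0 + n_perm)


def env_correlations(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    perm_below_n: int = 21,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Spearman rho and two-sided p for every (feature, covariate) pair.

    Tie-corrected ranks; for small n (< ``perm_below_n``) the p-value comes
    from a permutation null rather than the t approximation. Constant columns
    yield missing entries with a note.
    """
    feats = features.loc[covariates.index] if not features.index.equals(covariates.index) else features
    if len(feats) < 5:
        raise InvalidArgumentError("need at least 5 samples")
    rows = []
    for f in feats.columns:
        for c in covariates.columns:
            x = feats[f].to_numpy(dtype=float)
            y = covariates[c].to_numpy(dtype=float)
            if np.isnan(x).any() or np.isnan(y).any():
                raise InvalidArgumentError(f"missing values in {f!r} or {c!r}")
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((f, c, np.nan, np.nan, "constant column"))
                continue
            res = spearmanr(x, y)
            rho = float(res.statistic)
            if len(x) < perm_below_n:
                p = _spearman_perm_p(x, y, rho, 0 if seed is None else seed)
            else:
                p = float(res.pvalue)
            rows.append((f, c, rho, p, ""))
    return pd.DataFrame(rows, columns=["feature", "covariate", "rho", "p", "note"])
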