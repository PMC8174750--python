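"""Geographic distances and distance-decay statistics.

Great-circle distances come from the Haversine formula on a sphere of
radius 6,378.137 km.  Distance decay of community similarity is tested
with Mantel tests, Mantel correlograms (Sturges classes, progressive
Holm correction, half-maximum cutoff) and multiple regression on
distance matrices (MRM), with an optional variant excluding pairs at
zero geographic distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from ._utils import (
    as_rng,
    condensed_index,
    perm_pvalue,
    permute_condensed,
    random_permutations,
)
from .multivariate import PermTestResult, _permute as _chunked, _seed_int

EARTH_RADIUS_KM = 6378.137

_CHUNK = 256


def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in kilometres between decimal-degree
    coordinates; vectorized over array inputs."""
    lat1, lon1, lat2, lon2 = map(np.asarray, (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any((lon < -180) | (lon > 180)):
            raise ValueError("longitude outside [-180, 180]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    out = 2 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def geo_matrix(meta: pd.DataFrame, radius: float = EARTH_RADIUS_KM) -> DistanceMatrix:
    """Pairwise great-circle distances between samples; samples from the
    same site are at distance zero."""
    for col in ("latitude", "longitude"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks a {col!r} column")
        if meta[col].isna().any():
            missing = meta.index[meta[col].isna()].tolist()
            raise ValueError(f"missing coordinates for samples: {missing[:10]}")
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :], radius)
    d = np.asarray(d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    ids = [str(s) for s in (meta["sample_id"] if "sample_id" in meta.columns else meta.index)]
    return DistanceMatrix(d, ids=ids)


def _aligned_condensed(da: DistanceMatrix, db: DistanceMatrix):
    if list(da.ids) != list(db.ids):
        if set(da.ids) != set(db.ids):
            raise ValueError("distance matrices cover different sample sets")
        db = db.filter(da.ids)
    return np.asarray(da.data, float), np.asarray(db.data, float)


def _pearson_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between vector ``a`` and each row of ``b``."""
    ac = a - a.mean()
    bc = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((ac**2).sum() * (bc**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (bc @ ac) / denom
    return np.where(np.isfinite(r), r, 0.0)


def mantel(
    dA: DistanceMatrix,
    dB: DistanceMatrix,
    n_perm: int = 9999,
    method: str = "pearson",
    seed=None,
    exact: bool = False,
) -> PermTestResult:
    """Mantel correlation between two distance matrices.

    r is the (Pearson by default, Spearman optional) correlation of the
    upper-triangle vectors; the p-value permutes one matrix's rows and
    columns jointly, one-sided for r >= observed.
    """
    a, b = _aligned_condensed(dA, dB)
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    iu, ju = condensed_index(n)
    av, bsq = a[iu, ju], b
    if method == "spearman":
        av = stats.rankdata(av)
        bsq = _rank_square(b, n)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    bv = bsq[iu, ju]
    observed = float(_pearson_vec(av, bv[None])[0])

    def stat(perms):
        return _pearson_vec(av, permute_condensed(bsq, perms))

    p, used = _chunked(stat, n, n_perm, seed, exact)
    return PermTestResult(observed, perm_pvalue(observed, p, exact), used,
                          _seed_int(seed), f"mantel_{method}")


def _rank_square(b: np.ndarray, n: int) -> np.ndarray:
    iu, ju = condensed_index(n)
    out = np.zeros_like(b)
    r = stats.rankdata(b[iu, ju])
    out[iu, ju] = r
    out[ju, iu] = r
    return out


@dataclass(frozen=True)
class CorrelogramResult:
    """Per-distance-class Mantel statistics.

    ``mantel_r`` is signed so that positive values mean samples within
    the class are more similar than average; classes beyond half the
    maximum distance are reported but untested (NaN p)."""

    class_midpoints: np.ndarray
    class_counts: np.ndarray
    mantel_r: np.ndarray
    p_values: np.ndarray
    adjusted_p: np.ndarray
    breaks: np.ndarray
    n_permutations: int
    seed: int | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_midpoint_km": self.class_midpoints,
                "n_pairs": self.class_counts,
                "mantel_r": self.mantel_r,
                "p_value": self.p_values,
                "adjusted_p": self.adjusted_p,
            }
        )


def mantel_correlogram(
    dComm: DistanceMatrix,
    geo: DistanceMatrix,
    n_classes: int | None = None,
    n_perm: int = 9999,
    seed=None,
    cutoff: bool = True,
) -> CorrelogramResult:
    """Mantel correlogram of community distance against geographic
    distance classes.

    Classes follow Sturges' rule on the pair distances unless
    ``n_classes`` is given; per-class r correlates the community matrix
    with the class-membership indicator (sign flipped so positive means
    within-class similarity); p-values get the progressive Holm
    correction, and classes past half the maximum distance are left
    untested when ``cutoff`` is set.
    """
    c, g = _aligned_condensed(dComm, geo)
    n = c.shape[0]
    iu, ju = condensed_index(n)
    cv, gv = c[iu, ju], g[iu, ju]
    n_pairs = len(gv)
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(n_pairs) + 1))  # Sturges
    breaks = np.linspace(gv.min(), gv.max(), n_classes + 1)
    which = np.clip(np.digitize(gv, breaks[1:-1]), 0, n_classes - 1)
    midpoints = (breaks[:-1] + breaks[1:]) / 2
    counts = np.bincount(which, minlength=n_classes)
    half_max = gv.max() / 2
    rng = as_rng(seed)
    rs = np.full(n_classes, np.nan)
    ps = np.full(n_classes, np.nan)
    for k in range(n_classes):
        if counts[k] == 0:
            continue
        indicator = np.zeros((n, n))
        indicator[iu[which == k], ju[which == k]] = 1.0
        indicator += indicator.T
        iv = indicator[iu, ju]
        # negative correlation with membership == similarity within class
        observed = -float(_pearson_vec(iv, cv[None])[0])
        rs[k] = observed
        if cutoff and midpoints[k] > half_max:
            continue

        def stat(perms, iv=iv):
            return -_pearson_vec(iv, permute_condensed(c, perms))

        perm_stats, used = _chunked(stat, n, n_perm, rng, exact=False)
        # two-sided: as extreme in absolute value
        hits = np.sum(np.abs(perm_stats) >= abs(observed) - 1e-12)
        ps[k] = (1 + hits) / (1 + used)
    adjusted = _progressive_holm(ps)
    return CorrelogramResult(midpoints, counts, rs, ps, adjusted, breaks,
                             n_perm, _seed_int(seed))


def _progressive_holm(p: np.ndarray) -> np.ndarray:
    """Holm correction applied progressively: class k is corrected using
    only the first k tested classes."""
    out = np.full_like(p, np.nan)
    tested = []
    for k, pk in enumerate(p):
        if np.isnan(pk):
            continue
        tested.append(pk)
        arr = np.asarray(tested)
        order = np.argsort(arr)
        m = len(arr)
        adj = np.empty(m)
        running = 0.0
        for rank_idx, idx in enumerate(order):
            running = max(running, (m - rank_idx) * arr[idx])
            adj[idx] = min(1.0, running)
        out[k] = adj[-1]
    return out


@dataclass(frozen=True)
class MRMResult:
    coefficients: pd.Series
    r_squared: float
    coef_p_values: pd.Series
    r_squared_p: float
    n_permutations: int
    seed: int | None

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"coefficient": self.coefficients, "p_value": self.coef_p_values}
        )
        df.attrs["r_squared"] = self.r_squared
        return df


def mrm(
    dResp: DistanceMatrix,
    dPreds: list[DistanceMatrix] | DistanceMatrix,
    n_perm: int = 9999,
    seed=None,
    names: list[str] | None = None,
    exact: bool = False,
) -> MRMResult:
    """Multiple regression on distance matrices.

    OLS of the unfolded response pairs on unfolded predictor pairs;
    p-values permute the response matrix's rows/columns jointly and
    refit (two-sided on coefficients, one-sided on R^2).  With
    ``exact=True`` all sample relabelings are enumerated (small n).
    """
    if isinstance(dPreds, DistanceMatrix):
        dPreds = [dPreds]
    if not dPreds:
        raise ValueError("need at least one predictor matrix")
    n = len(dResp.ids)
    iu, ju = condensed_index(n)
    cols = []
    for dp in dPreds:
        r, p = _aligned_condensed(dResp, dp)
        cols.append(p[iu, ju])
    resp_sq = np.asarray(dResp.data, float)
    y = resp_sq[iu, ju]
    x = np.column_stack([np.ones(len(y))] + cols)
    cond = np.linalg.cond(x)
    if cond > 1e10:
        raise ValueError(
            f"predictor matrices are collinear (condition number {cond:.3g})"
        )
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    fitted = x @ beta
    ss_res = ((y - fitted) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if names is None:
        names = [f"x{i + 1}" for i in range(len(dPreds))]
    index = ["intercept"] + list(names)

    def stats_for(perms: np.ndarray):
        yp = permute_condensed(resp_sq, perms)  # (b, n_pairs)
        bp = yp @ pinv.T  # (b, k+1)
        fit = bp @ x.T
        ssr = ((yp - fit) ** 2).sum(axis=1)
        sst = ((yp - yp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2p = 1.0 - ssr / sst
        return bp, r2p

    coef_hits = np.zeros(len(beta))
    r2_hits = 0
    if exact:
        from ._utils import all_permutations

        perms = all_permutations(n)
        total = len(perms)
        for i in range(0, total, _CHUNK):
            bp, r2p = stats_for(perms[i : i + _CHUNK])
            coef_hits += (np.abs(bp) >= np.abs(beta)[None, :] - 1e-12).sum(axis=0)
            r2_hits += int(np.sum(r2p >= r2 - 1e-12))
        coef_p = coef_hits / total
        r2_p = r2_hits / total
        used = total
    else:
        rng = as_rng(seed)
        done = 0
        while done < n_perm:
            b = min(_CHUNK, n_perm - done)
            bp, r2p = stats_for(random_permutations(rng, n, b))
            coef_hits += (np.abs(bp) >= np.abs(beta)[None, :] - 1e-12).sum(axis=0)
            r2_hits += int(np.sum(r2p >= r2 - 1e-12))
            done += b
        coef_p = (1 + coef_hits) / (1 + n_perm)
        r2_p = (1 + r2_hits) / (1 + n_perm)
        used = n_perm
    coef_p[0] = np.nan  # intercept not tested
    return MRMResult(
        pd.Series(beta, index=index),
        float(r2),
        pd.Series(coef_p, index=index),
        float(r2_p),
        used,
        _seed_int(seed),
    )


def mask_zero_geo(dComm: DistanceMatrix, geo: DistanceMatrix):
    """Boolean mask (condensed ordering) of sample pairs at nonzero
    geographic distance, with the retained pair count."""
    c, g = _aligned_condensed(dComm, geo)
    iu, ju = condensed_index(c.shape[0])
    mask = g[iu, ju] > 0
    if not mask.any():
        raise ValueError("all sample pairs are at zero geographic distance")
    return mask, int(mask.sum())


def mantel_masked(
    dComm: DistanceMatrix,
    geo: DistanceMatrix,
    n_perm: int = 9999,
    method: str = "pearson",
    seed=None,
) -> PermTestResult:
    """Mantel test excluding pairs at zero geographic distance.

    The permutation scheme still relabels whole samples (respecting the
    matrix structure); the retained-pair correlation is recomputed for
    each relabeling against the fixed geographic matrix and mask.
    """
    c, g = _aligned_condensed(dComm, geo)
    n = c.shape[0]
    iu, ju = condensed_index(n)
    mask, _ = mask_zero_geo(dComm, geo)
    gv = g[iu, ju][mask]
    if method == "spearman":
        gv = stats.rankdata(gv)

    def corr(cvals: np.ndarray) -> np.ndarray:
        kept = cvals[..., mask]
        if method == "spearman":
            kept = np.apply_along_axis(stats.rankdata, -1, kept)
        return _pearson_vec(gv, kept if kept.ndim == 2 else kept[None])

    observed = float(corr(c[iu, ju])[0])
    rng = as_rng(seed)
    hits = 0
    done = 0
    while done < n_perm:
        b = min(_CHUNK, n_perm - done)
        perms = random_permutations(rng, n, b)
        stats_b = corr(permute_condensed(c, perms))
        hits += int(np.sum(stats_b >= observed - 1e-12))
        done += b
    p = (1 + hits) / (1 + n_perm)
    return PermTestResult(observed, p, n_perm, _seed_int(seed),
                          f"mantel_masked_{method}")
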