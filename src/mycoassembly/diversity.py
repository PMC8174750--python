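"""Alpha diversity, compositional transforms, beta-diversity distance
matrices, and principal-coordinate analysis.

Distance matrices are carried as :class:`skbio.DistanceMatrix`, the
field's standard container, and serialized as square TSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.linalg import eigh
from skbio import DistanceMatrix

from .data_io import CountTable

BETA_METRICS = ("bray_curtis", "aitchison", "hellinger")


def shannon(counts, base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i over positive proportions.

    Natural log by default; zero for a vector dominated by one taxon.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("shannon expects a 1-D count vector")
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("cannot compute Shannon index of an all-zero vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def alpha_diversity(table: CountTable, base: float | None = None) -> pd.Series:
    """Per-sample Shannon index of a count table."""
    return pd.Series(
        [shannon(row, base=base) for row in table.matrix()],
        index=table.sample_ids,
        name="shannon",
    )


def _matrix(table) -> np.ndarray:
    if isinstance(table, CountTable):
        return table.matrix().astype(float)
    return np.asarray(table, dtype=float)


def to_proportions(table) -> np.ndarray:
    """Close each sample's counts to relative abundances summing to 1."""
    x = _matrix(table)
    sums = x.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("all-zero sample row; drop empty samples first")
    return x / sums[:, None]


def transform_clr(table, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform after adding a pseudocount.

    Counts are shifted by ``pseudocount``, closed to proportions, and
    log-centered per sample; every output row sums to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = _matrix(table) + pseudocount
    logx = np.log(x / x.sum(axis=1, keepdims=True))
    return logx - logx.mean(axis=1, keepdims=True)


def transform_hellinger(table) -> np.ndarray:
    """Square root of relative abundances; rows have unit squared sum."""
    return np.sqrt(to_proportions(table))


def beta_distance(
    table,
    metric: str = "bray_curtis",
    pseudocount: float = 1.0,
    on_proportions: bool = False,
    ids=None,
) -> DistanceMatrix:
    """Pairwise sample dissimilarities.

    bray_curtis : sum|x-y| / sum(x+y), by default on raw counts (the
        convention of ecological ordination stacks); ``on_proportions``
        closes rows first.
    aitchison : Euclidean distance between clr-transformed rows.
    hellinger : Euclidean distance between sqrt-proportion rows.
    """
    if isinstance(table, CountTable):
        if ids is None:
            ids = table.sample_ids
    x = _matrix(table)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    if ids is None:
        ids = [str(i) for i in range(x.shape[0])]
    if metric == "bray_curtis":
        data = to_proportions(x) if on_proportions else x
        condensed = pdist(data, metric="braycurtis")
    elif metric == "aitchison":
        condensed = pdist(transform_clr(x, pseudocount), metric="euclidean")
    elif metric == "hellinger":
        condensed = pdist(transform_hellinger(x), metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {BETA_METRICS}")
    return DistanceMatrix(squareform(condensed, checks=False), ids=ids)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


@dataclass(frozen=True)
class Ordination:
    """Classical-scaling result: coordinates for positive eigenvalues,
    all eigenvalues reported (including negative ones) in descending
    order."""

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = np.clip(self.eigenvalues, 0, None)
        return pos / pos.sum() if pos.sum() > 0 else pos


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered matrix -1/2 J D^2 J used by classical scaling and
    the distance-based ANOVA partitioning."""
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, correction: str | None = None) -> Ordination:
    """Principal-coordinate analysis (classical multidimensional
    scaling).

    Axes are returned for positive eigenvalues only; negative
    eigenvalues (non-Euclidean input) are reported, not corrected,
    unless ``correction='cailliez'``.
    """
    d = np.asarray(dm.data, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if correction == "cailliez":
        d = _cailliez(d)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    g = gower_center(d)
    vals, vecs = eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1, d.shape[0]) * np.finfo(float).eps * max(abs(vals).max(), 1.0)
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return Ordination(
        sample_ids=list(dm.ids), coordinates=coords, eigenvalues=vals
    )


def _cailliez(d: np.ndarray) -> np.ndarray:
    """Smallest additive constant making the matrix Euclidean-embeddable."""
    n = d.shape[0]
    zero = np.zeros((n, n))
    ident = np.eye(n)

    def _center(a):
        row = a.mean(axis=1, keepdims=True)
        col = a.mean(axis=0, keepdims=True)
        return a - row - col + a.mean()

    delta1 = _center(-0.5 * d**2)
    delta2 = _center(-0.5 * d)
    # c = largest eigenvalue of the companion block matrix
    top = np.hstack([zero, 2 * delta1])
    bottom = np.hstack([-ident, -4 * delta2])
    eigs = np.linalg.eigvals(np.vstack([top, bottom]))
    c = float(np.max(eigs.real))
    if c <= 0:
        return d
    out = d + c
    np.fill_diagonal(out, 0.0)
    return out
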