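"""Permutation-based group-difference tests.

Scalar responses get Kruskal-Wallis with Dunn post hoc; distance
matrices get PERMANOVA (location) and PERMDISP (dispersion) with
pairwise / Tukey HSD follow-ups.  All permutation p-values follow the
add-one rule (1 + #extreme)/(1 + B) and are reproducible under a fixed
seed; ``exact=True`` switches to exhaustive enumeration of label
permutations (small n only), in which case the identity permutation is
part of the reference set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from ._utils import (
    all_permutations,
    as_rng,
    bonferroni,
    perm_pvalue,
    random_permutations,
)
from .diversity import gower_center

_CHUNK = 512  # permutations processed per vectorized block


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    name: str = ""

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "test": self.name,
                "statistic": self.statistic,
                "p_value": self.p_value,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
            }
        )


def _check_groups(groups) -> tuple[np.ndarray, list, np.ndarray]:
    labels = np.asarray(groups)
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    return labels, list(uniq), inv


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float((counts**3 - counts).sum())


def _kw_h(ranks: np.ndarray, onehot: np.ndarray, sizes: np.ndarray, c: float) -> np.ndarray:
    """Kruskal-Wallis H for each row of ``ranks`` ((B, n) permuted midranks)."""
    n = ranks.shape[-1]
    sums = ranks @ onehot  # (B, k)
    h = 12.0 / (n * (n + 1)) * (sums**2 / sizes).sum(axis=-1) - 3 * (n + 1)
    return h / c if c > 0 else np.zeros_like(h)


def kruskal_wallis(
    values, groups, n_perm: int = 9999, seed=None, exact: bool = False
) -> PermTestResult:
    """Kruskal-Wallis H on midranks (tie-corrected) with a permutation
    p-value instead of the chi-square approximation."""
    x = np.asarray(values, dtype=float)
    labels, uniq, inv = _check_groups(groups)
    if len(labels) != len(x):
        raise ValueError("values and groups must align")
    n = len(x)
    ranks = stats.rankdata(x)
    onehot = np.eye(len(uniq))[inv]
    sizes = onehot.sum(axis=0)
    c = 1.0 - _tie_term(x) / (n**3 - n)
    observed = float(_kw_h(ranks[None, :], onehot, sizes, c)[0])

    def stat(perms: np.ndarray) -> np.ndarray:
        return _kw_h(ranks[perms], onehot, sizes, c)

    p, used = _permute(stat, n, n_perm, seed, exact)
    return PermTestResult(observed, perm_pvalue(observed, p, exact), used,
                          _seed_int(seed), "kruskal_wallis")


def dunn_posthoc(values, groups, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z tests on mean ranks with tie-corrected pooled
    variance; Bonferroni-adjusted over all group pairs."""
    if adjust != "bonferroni":
        raise ValueError("only Bonferroni adjustment is built in")
    x = np.asarray(values, dtype=float)
    labels, uniq, inv = _check_groups(groups)
    n = len(x)
    ranks = stats.rankdata(x)
    mean_ranks = {g: ranks[labels == g].mean() for g in uniq}
    sizes = {g: int((labels == g).sum()) for g in uniq}
    pooled = n * (n + 1) / 12.0 - _tie_term(x) / (12.0 * (n - 1))
    rows = []
    for a, b in combinations(uniq, 2):
        se = np.sqrt(pooled * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append((a, b, z, p))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "raw_p"])
    table["adjusted_p"] = bonferroni(table["raw_p"].to_numpy())
    return table


def _pseudo_f(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """PERMANOVA pseudo-F for each permuted one-hot block (B, n, k)."""
    n = d2.shape[0]
    k = sizes.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = np.zeros(onehot.shape[0])
    for g in range(k):
        v = onehot[:, :, g]
        ss_within += np.einsum("bi,ij,bj->b", v, d2, v) / (2.0 * sizes[g])
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    dm: DistanceMatrix, groups, n_perm: int = 9999, seed=None, exact: bool = False
) -> PermTestResult:
    """Distance-based one-way multivariate ANOVA (Anderson's pseudo-F
    from within/between sums of squared distances), p by free label
    permutation."""
    labels, uniq, inv = _check_groups(groups)
    n = len(dm.ids)
    if len(labels) != n:
        raise ValueError("groups must align with the distance matrix")
    k = len(uniq)
    sizes = np.bincount(inv).astype(float)
    if n - k < 1:
        raise ValueError("every group is a singleton; pseudo-F undefined")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    onehot = np.eye(k)[inv]
    observed = float(_pseudo_f(d2, onehot[None], sizes)[0])

    def stat(perms: np.ndarray) -> np.ndarray:
        return _pseudo_f(d2, onehot[perms], sizes)

    p, used = _permute(stat, n, n_perm, seed, exact)
    return PermTestResult(observed, perm_pvalue(observed, p, exact), used,
                          _seed_int(seed), "permanova")


def pairwise_permanova(
    dm: DistanceMatrix, groups, n_perm: int = 9999, seed=None, exact: bool = False
) -> pd.DataFrame:
    """PERMANOVA on each pair of groups, Bonferroni-adjusted."""
    labels, uniq, _ = _check_groups(groups)
    ids = np.asarray(dm.ids)
    rng = as_rng(seed)
    rows = []
    for a, b in combinations(uniq, 2):
        mask = (labels == a) | (labels == b)
        sub = dm.filter(ids[mask])
        res = permanova(sub, labels[mask], n_perm=n_perm,
                        seed=rng.integers(2**31), exact=exact)
        rows.append((a, b, res.statistic, res.p_value))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "raw_p"])
    table["adjusted_p"] = bonferroni(table["raw_p"].to_numpy())
    return table


def _centroid_dist_from_gower(g: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Centroid distances for each permuted one-hot block (B, n, k).

    Works directly on the Gower-centered matrix, whose (possibly
    indefinite) inner products carry Anderson's negative-eigenvalue
    correction: d^2(i, c_g) = G_ii - 2 (G v)_i / n_g + v' G v / n_g^2.
    Squared distances are clipped at zero before the square root.
    """
    sizes = onehot[0].sum(axis=0)
    if g.ndim == 2:
        diag = np.diag(g)[None, :, None]
        cross = np.einsum("ij,bjk->bik", g, onehot)  # (B, n, k)
    else:
        diag = np.einsum("bii->bi", g)[:, :, None]
        cross = np.einsum("bij,bjk->bik", g, onehot)
    gram = np.einsum("bik,bik->bk", onehot, cross)  # v' G v per group
    d2 = diag - 2.0 * cross / sizes[None, None, :] + (gram / sizes**2)[:, None, :]
    member_d2 = (d2 * onehot).sum(axis=2)  # pick own group's distance
    return np.sqrt(np.clip(member_d2, 0.0, None))


def centroid_distances(dm: DistanceMatrix, groups) -> pd.Series:
    """Distance of each sample to its group centroid in PCoA space with
    Anderson's negative-eigenvalue correction (squared real-part minus
    squared imaginary-part contributions)."""
    labels, uniq, inv = _check_groups(groups)
    g = gower_center(np.asarray(dm.data, dtype=float))
    onehot = np.eye(len(uniq))[inv]
    out = _centroid_dist_from_gower(g, onehot[None])[0]
    return pd.Series(out, index=list(dm.ids), name="centroid_distance")


def _anova_f(values: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """One-way ANOVA F for each row of (B, n) ``values``."""
    n = values.shape[-1]
    k = sizes.shape[0]
    sums = values @ onehot
    ss_groups = (sums**2 / sizes).sum(axis=-1) - values.sum(axis=-1) ** 2 / n
    ss_total = (values**2).sum(axis=-1) - values.sum(axis=-1) ** 2 / n
    ss_resid = ss_total - ss_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_groups / (k - 1)) / (ss_resid / (n - k))
    return np.where(np.isfinite(f), f, 0.0)


def permdisp(
    dm: DistanceMatrix, groups, n_perm: int = 9999, seed=None, exact: bool = False
) -> tuple[PermTestResult, pd.Series]:
    """Homogeneity-of-dispersion test: ANOVA F on distances to group
    centroids, p by permuting group labels with the centroid distances
    recomputed for every relabeling (so the reference distribution does
    not inherit the observed grouping's centroids).

    Returns the test result together with the per-sample centroid
    distances (useful for Tukey HSD follow-up).
    """
    labels, uniq, inv = _check_groups(groups)
    g = gower_center(np.asarray(dm.data, dtype=float))
    n = g.shape[0]
    onehot = np.eye(len(uniq))[inv]
    sizes = onehot.sum(axis=0)
    x = _centroid_dist_from_gower(g, onehot[None])[0]
    dists = pd.Series(x, index=list(dm.ids), name="centroid_distance")
    observed = float(_anova_f(x[None], onehot, sizes)[0])

    def stat(perms: np.ndarray) -> np.ndarray:
        # slot i of each permutation holds sample perms[b, i]; slots keep
        # the fixed group pattern, so permuting the Gower matrix assigns
        # samples to groups and the z's are recomputed per relabeling
        gp = g[perms[:, :, None], perms[:, None, :]]  # (B, n, n)
        oh = np.broadcast_to(onehot, (len(perms), n, onehot.shape[1]))
        z = _centroid_dist_from_gower(gp, oh)
        return _anova_f(z, onehot, sizes)

    p, used = _permute(stat, n, n_perm, seed, exact, memory_cells=n * n)
    result = PermTestResult(observed, perm_pvalue(observed, p, exact), used,
                            _seed_int(seed), "permdisp")
    return result, dists


def tukey_hsd(centroid_dists, groups) -> pd.DataFrame:
    """Tukey's honestly-significant-difference comparisons of mean
    centroid distances between groups (studentized range)."""
    x = np.asarray(centroid_dists, dtype=float)
    labels, uniq, _ = _check_groups(groups)
    samples = [x[labels == g] for g in uniq]
    for g, s in zip(uniq, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    res = stats.tukey_hsd(*samples)
    rows = []
    for i, j in combinations(range(len(uniq)), 2):
        rows.append(
            (uniq[i], uniq[j], res.statistic[i, j], res.pvalue[i, j], res.pvalue[i, j])
        )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "statistic", "raw_p", "adjusted_p"]
    )


def _permute(stat_fn, n: int, n_perm: int, seed, exact: bool, memory_cells=None):
    """Evaluate a vectorized statistic over permutations, chunked.

    ``memory_cells`` caps the chunk size for statistics that materialize
    per-permutation work proportional to that many array cells.
    """
    chunk = _CHUNK
    if memory_cells:
        chunk = max(1, min(_CHUNK, int(1e7 / memory_cells)))
    if exact:
        perms = all_permutations(n)
        out = np.concatenate(
            [stat_fn(perms[i : i + chunk]) for i in range(0, len(perms), chunk)]
        )
        return out, len(perms)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = as_rng(seed)
    chunks = []
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        chunks.append(stat_fn(random_permutations(rng, n, b)))
        done += b
    return np.concatenate(chunks), n_perm


def _seed_int(seed):
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return None
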