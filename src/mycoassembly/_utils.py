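"""Internal helpers shared across modules: RNG handling and condensed
distance bookkeeping."""

from __future__ import annotations

import itertools

import numpy as np

# Counting rule for "permuted statistic at least as extreme as observed":
# a tiny relative tolerance keeps exact ties (common with rank statistics
# and exhaustive enumeration) on the conservative side of the count.
_TIE_EPS = 1e-9


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from an int seed, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def count_ge(perm_stats: np.ndarray, observed: float) -> int:
    tol = _TIE_EPS * max(1.0, abs(observed))
    return int(np.sum(perm_stats >= observed - tol))


def perm_pvalue(observed: float, perm_stats: np.ndarray, exhaustive: bool) -> float:
    """One-sided (greater) permutation p-value.

    Random permutations use the add-one rule (1 + #extreme)/(1 + B); an
    exhaustive enumeration already contains the identity permutation, so
    the plain fraction is used.
    """
    b = len(perm_stats)
    hits = count_ge(perm_stats, observed)
    if exhaustive:
        return hits / b
    return (1 + hits) / (1 + b)


def random_permutations(rng: np.random.Generator, n: int, b: int) -> np.ndarray:
    """(b, n) array of random permutations of range(n)."""
    out = np.tile(np.arange(n), (b, 1))
    return rng.permuted(out, axis=1)


def all_permutations(n: int, limit: int = 8) -> np.ndarray:
    if n > limit:
        raise ValueError(
            f"exhaustive enumeration limited to n <= {limit}; got n = {n}"
        )
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def condensed_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices (i < j) matching scipy's condensed ordering."""
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju


def permute_condensed(square: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Condensed upper triangles of square[p][:, p] for each permutation p.

    Returns a (B, n_pairs) array.  ``perms`` maps new position -> old index.
    """
    n = square.shape[0]
    iu, ju = condensed_index(n)
    return square[perms[:, iu], perms[:, ju]]


def bonferroni(p: np.ndarray) -> np.ndarray:
    return np.minimum(1.0, p * len(p))
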