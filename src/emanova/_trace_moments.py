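"""Exact permutation moments of trace statistics of double-centered matrices.

The permutation null of a statistic ``T(pi) = tr(G P K P^T)`` -- with ``P``
the permutation matrix of ``pi``, and ``G``, ``K`` symmetric double-centered
(zero row/column sums) -- has closed-form raw moments.  Writing

    T(pi) = sum_{i,j} G_{ij} K_{pi(i),pi(j)},

the m-th raw moment over the uniform distribution on all n! permutations is

    E[T^m] = sum_{rho} N_rho(G) * N_rho(K) / (n)_{|rho|},

where ``rho`` runs over set partitions of the 2m index slots of the m
``G``-factors, ``N_rho(A)`` is the sum of the corresponding entry products
over *distinct* index assignments to the blocks of ``rho``, and ``(n)_k`` is
the falling factorial.  The distinct-index sums are recovered from
unrestricted ("free") sums by Moebius inversion on the partition lattice;
for the partition lattice the Moebius function of an interval is the product
over merged blocks of ``(-1)^(k-1) (k-1)!``.

Because both matrices have zero row sums, every free sum whose partition
contains a singleton block vanishes identically: a singleton slot is a free
index summed over a full row or column.  Only partitions with all blocks of
size >= 2 are ever evaluated (1, 4 and 41 partitions for m = 1, 2, 3), each
as a small einsum contraction, so the whole computation is a few hundred
matrix contractions of cost at most O(n^3) -- no sampling anywhere.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["MomentEngine", "trace_moment", "permutation_moments"]


def _set_partitions(items: tuple[int, ...]):
    """Yield all set partitions of ``items`` as tuples of sorted-tuple blocks."""
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for sub in _set_partitions(rest):
        # first in its own block
        yield ((first,),) + sub
        # first joins an existing block
        for i, block in enumerate(sub):
            yield sub[:i] + ((first,) + block,) + sub[i + 1 :]


def _canonical(partition) -> tuple[tuple[int, ...], ...]:
    return tuple(sorted(tuple(sorted(b)) for b in partition))


def _einsum_subscript(partition, m: int) -> str:
    letter = {}
    for b, block in enumerate(partition):
        for slot in block:
            letter[slot] = chr(ord("a") + b)
    factors = [letter[2 * t] + letter[2 * t + 1] for t in range(m)]
    return ",".join(factors) + "->"


@lru_cache(maxsize=None)
def _structure(m: int):
    """Precompute the partition lattice data for the m-th moment.

    Returns (subs, C, sizes) where ``subs`` are einsum subscripts for the
    singleton-free partitions, ``C`` maps the vector of free sums to the
    vector of distinct sums ``N_rho`` over *all* partitions (Moebius
    inversion, with singleton-block free sums structurally zero), and
    ``sizes[rho]`` is the number of blocks of rho.
    """
    slots = tuple(range(2 * m))
    parts = sorted({_canonical(p) for p in _set_partitions(slots)})
    index = {p: i for i, p in enumerate(parts)}
    nonsing = [i for i, p in enumerate(parts) if all(len(b) >= 2 for b in p)]
    col_of = {i: j for j, i in enumerate(nonsing)}

    C = np.zeros((len(parts), len(nonsing)))
    fact = [1, 1, 2, 6, 24, 120, 720]
    for i, rho in enumerate(parts):
        blocks = list(rho)
        # coarsenings of rho <-> set partitions of its block list
        for grouping in _set_partitions(tuple(range(len(blocks)))):
            merged = _canonical(
                tuple(sum((blocks[b] for b in grp), ()) for grp in grouping)
            )
            j = index[merged]
            if j not in col_of:
                continue  # singleton block => free sum is 0 for centered input
            mu = 1
            for grp in grouping:
                k = len(grp)
                mu *= (-1) ** (k - 1) * fact[k - 1]
            C[i, col_of[j]] += mu

    sizes = np.array([len(p) for p in parts])
    subs = [_einsum_subscript(parts[i], m) for i in nonsing]
    return subs, C, sizes


@lru_cache(maxsize=None)
def _einsum_path(sub: str, n: int, m: int):
    ops = [np.empty((n, n))] * m
    return np.einsum_path(sub, *ops, optimize="optimal")[0]


def _free_sums(A: np.ndarray, m: int) -> np.ndarray:
    subs, _, _ = _structure(m)
    n = A.shape[0]
    ops = [A] * m
    return np.array(
        [np.einsum(s, *ops, optimize=_einsum_path(s, n, m)) for s in subs]
    )


@lru_cache(maxsize=None)
def _weight_matrix_cached(m: int, n: int):
    _, C, sizes = _structure(m)
    w = np.zeros(len(sizes))
    for i, k in enumerate(sizes):
        if k <= n:
            ff = 1.0
            for j in range(k):
                ff *= n - j
            w[i] = 1.0 / ff
        # partitions with more blocks than n admit no distinct assignment
    return C.T @ (w[:, None] * C)


def _check_centered(A: np.ndarray, name: str) -> np.ndarray:
    scale = np.abs(A).max()
    if scale == 0:
        return A
    rows = A.sum(axis=1)
    if np.abs(rows).max() > 1e-6 * scale * A.shape[0]:
        raise ValueError(
            f"{name} must be double-centered (zero row sums); "
            f"max |row sum| = {np.abs(rows).max():.3g}"
        )
    # project out the residual centering noise so the structural zeros of the
    # closed form are exact
    col = A.mean(axis=0)
    A = A - col[None, :] - col[:, None] + col.mean()
    return A


class MomentEngine:
    """Exact permutation moments of ``tr(G P K P^T)`` for a fixed target ``G``.

    Precomputes the free-sum vectors of ``G`` once so that moments against
    many kernels (the powered kernels of an ensemble run) cost one set of
    kernel contractions each.
    """

    def __init__(self, G: np.ndarray):
        G = np.asarray(G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("G must be square")
        G = _check_centered(0.5 * (G + G.T), "G")
        self.n = G.shape[0]
        self._fG = {m: _free_sums(G, m) for m in (1, 2, 3)}
        self._Q = {m: _weight_matrix_cached(m, self.n) for m in (1, 2, 3)}

    def raw_moment(self, K: np.ndarray, m: int) -> float:
        fK = _free_sums(K, m)
        return float(self._fG[m] @ self._Q[m] @ fK)

    def moments(self, K: np.ndarray) -> tuple[float, float, float]:
        """Return ``(E1, Var, E3)``: mean, variance and third raw moment."""
        K = np.asarray(K, dtype=float)
        if K.shape != (self.n, self.n):
            raise ValueError("kernel shape mismatch")
        K = _check_centered(0.5 * (K + K.T), "K")
        E1 = self.raw_moment(K, 1)
        E2 = self.raw_moment(K, 2)
        E3 = self.raw_moment(K, 3)
        return E1, E2 - E1 * E1, E3


def trace_moment(G: np.ndarray, K: np.ndarray, m: int) -> float:
    """m-th raw permutation moment of ``tr(G P K P^T)`` (m = 1, 2 or 3)."""
    if m not in (1, 2, 3):
        raise ValueError("only moments of order 1..3 are implemented")
    eng = MomentEngine(G)
    K = _check_centered(0.5 * (np.asarray(K, float) + np.asarray(K, float).T), "K")
    return eng.raw_moment(K, m)


def permutation_moments(G: np.ndarray, K: np.ndarray) -> tuple[float, float, float]:
    """Exact ``(E1, Var, E3)`` of the permutation null of ``tr(G P K P^T)``."""
    return MomentEngine(G).moments(K)
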