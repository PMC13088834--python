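"""Permutation references: exhaustive enumeration and Monte Carlo p-values.

These are the normative checks for the analytic path: the closed-form
moments must reproduce :func:`exhaustive_moments` exactly (up to floating
point) at small n, and the Pearson type III p-values must track
:func:`mc_permutation_pvalue` within Monte Carlo error.  The oracle permutes
the kernel's rows and columns against a fixed projection contrast, the same
scheme under which the analytic moments are derived.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OracleReport",
    "exhaustive_moments",
    "mc_permutation_pvalue",
    "mc_permutation_pvalues",
]

_MAX_EXHAUSTIVE_N = 8


def exhaustive_moments(G: np.ndarray, Kr: np.ndarray) -> tuple[float, float, float]:
    """(E1, Var, E3) of ``tr(G P Kr P^T)`` by enumerating all n! permutations.

    Refuses n > 8 (40320 permutations is the practical ceiling).
    """
    G = np.asarray(G, dtype=float)
    Kr = np.asarray(Kr, dtype=float)
    n = G.shape[0]
    if n > _MAX_EXHAUSTIVE_N:
        raise ValueError(f"exhaustive enumeration limited to n <= {_MAX_EXHAUSTIVE_N}")
    total = t2 = t3 = 0.0
    for perm in itertools.permutations(range(n)):
        idx = np.asarray(perm)
        t = float(np.sum(G * Kr[np.ix_(idx, idx)]))
        total += t
        t2 += t * t
        t3 += t * t * t
    nfact = math.factorial(n)
    e1 = total / nfact
    return e1, t2 / nfact - e1 * e1, t3 / nfact


def _permuted_traces(
    G: np.ndarray, kernels: np.ndarray, B: int, rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """(len(kernels), B) array of tr(G P K P^T) over B random permutations."""
    n = G.shape[0]
    out = np.empty((kernels.shape[0], B))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        for k, K in enumerate(kernels):
            Kp = K[idx[:, :, None], idx[:, None, :]]
            out[k, done : done + b] = np.einsum("bij,ij->b", Kp, G)
        done += b
    return out


def mc_permutation_pvalue(
    G: np.ndarray,
    Kr: np.ndarray,
    B: int = 10000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Add-one Monte Carlo permutation p-value of ``T = tr(G Kr)``.

    ``p = (1 + #{b : T(pi_b) >= T_obs}) / (B + 1)``; never 0, never below
    ``1/(B+1)``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    G = np.asarray(G, dtype=float)
    Kr = np.asarray(Kr, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = float(np.sum(G * Kr))
    traces = _permuted_traces(G, Kr[None], B, rng)[0]
    return (1 + int(np.sum(traces >= t_obs))) / (B + 1)


def mc_permutation_pvalues(
    G: np.ndarray,
    kernels: list[np.ndarray],
    B: int = 10000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Add-one MC p-values for several kernels sharing one permutation stream."""
    if B < 100:
        raise ValueError("B must be at least 100")
    G = np.asarray(G, dtype=float)
    ks = np.stack([np.asarray(K, dtype=float) for K in kernels])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = np.einsum("kij,ij->k", ks, G)
    traces = _permuted_traces(G, ks, B, rng)
    return (1 + (traces >= t_obs[:, None]).sum(axis=1)) / (B + 1)


@dataclass
class OracleReport:
    """Comparison of the analytic path against permutation references."""

    n: int
    B: int
    exact_moments: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)

    @property
    def max_abs_pvalue_delta(self) -> float:
        return max((c["abs_delta"] for c in self.comparisons), default=0.0)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "B": self.B,
            "exact_moments": self.exact_moments,
            "comparisons": self.comparisons,
            "max_abs_pvalue_delta": self.max_abs_pvalue_delta,
        }
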