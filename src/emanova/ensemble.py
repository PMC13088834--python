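"""Cauchy combination of base tests into the single ensemble p-value.

Each base p-value is mapped through the Cauchy tail transform
``tan((0.5 - p) pi)``; the equally weighted average

    T = (1 / (D * R)) sum_{d,r} tan((0.5 - p_{d,r}) pi)

is standard Cauchy under the null *regardless of the dependence* between
base tests, so the final p-value is simply ``P = 0.5 - arctan(T)/pi``.  The
transform's heavy tail means any strongly significant base test dominates
the average, which is what makes the ensemble robust across distances and
spectrum exponents.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .base_test import (
    BaseTestResult,
    DegenerateDesignError,
    DegenerateNullError,
    _distance_for,
    _moment_scale,
    base_statistic,
    pearson3_pvalue,
    projection_matrices,
    skewness,
)
from ._trace_moments import MomentEngine
from .io_formats import AbundanceTable, PhyloTree
from .kernel import centered_kernel

logger = logging.getLogger(__name__)

__all__ = ["EnsembleResult", "cauchy_combine", "emanova"]

DEFAULT_D = (1, 2, 3)
DEFAULT_R = (0.125, 0.25, 0.5, 1.0, 2.0)
R_RECOMMENDED_RANGE = (0.125, 2.0)


def _cauchy_sf(T: float) -> float:
    """Standard-Cauchy upper tail, stable for |T| >> 1."""
    if T > 1.0:
        return float(np.arctan(1.0 / T) / np.pi)
    if T < -1.0:
        return float(1.0 + np.arctan(1.0 / T) / np.pi)
    return float(0.5 - np.arctan(T) / np.pi)


def cauchy_combine(pvals) -> tuple[float, float]:
    """Equal-weight Cauchy combination: returns ``(T_ens, P)``.

    Tangent terms are evaluated through the identity
    ``tan((0.5 - p) pi) = 1 / tan(p pi)``, which is numerically stable for
    the very small p-values the base tests can produce.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("p-values must lie strictly in (0, 1); callers clip")
    T = float(np.mean(1.0 / np.tan(np.pi * p)))
    return T, _cauchy_sf(T)


@dataclass
class EnsembleResult:
    """All base tests plus the combined statistic and final p-value."""

    base: list[BaseTestResult]
    T_ens: float
    P: float
    D_set: tuple[int, ...]
    R_set: tuple[float, ...]
    dropped: list[tuple[int, float]] = field(default_factory=list)


def emanova(
    table: AbundanceTable,
    tree: PhyloTree | None,
    X1: np.ndarray,
    X2: np.ndarray | None = None,
    D_set=DEFAULT_D,
    R_set=DEFAULT_R,
    alpha_unifrac: float = 0.5,
) -> EnsembleResult:
    """Run all D x R base tests and combine them into one p-value.

    One distance computation and one eigendecomposition per metric serve
    every exponent; the target-side moment contractions are shared across
    all kernels.  The whole path is deterministic: identical inputs give
    bit-identical results.
    """
    D_set = tuple(int(d) for d in D_set)
    R_set = tuple(float(r) for r in R_set)
    if len(set(D_set)) != len(D_set) or len(set(R_set)) != len(R_set):
        raise ValueError("duplicate entries in D_set or R_set")
    if not D_set or not R_set:
        raise ValueError("D_set and R_set must be nonempty")
    if tree is None and any(d in (1, 2) for d in D_set):
        raise ValueError("UniFrac distances (d=1,2) require a tree")
    lo, hi = R_RECOMMENDED_RANGE
    if any(r < lo or r > hi for r in R_set):
        warnings.warn(
            f"exponents outside [{lo}, {hi}] may cause approximation inaccuracy",
            stacklevel=2,
        )

    proj = projection_matrices(X1, X2)
    if proj.v == 0:
        raise DegenerateDesignError("X1 lies entirely inside span(X2)")
    engine = MomentEngine(proj.G)

    base: list[BaseTestResult] = []
    dropped: list[tuple[int, float]] = []
    for d in D_set:
        ck = centered_kernel(_distance_for(d, table, tree, alpha_unifrac))
        for r in R_set:
            Kr = ck.power(r)
            T = base_statistic(proj.G, Kr)
            E1, Var, E3 = engine.moments(Kr)
            try:
                g = skewness(E1, Var, E3, scale=_moment_scale(proj.G, Kr))
            except DegenerateNullError:
                logger.warning(
                    "base test (d=%d, r=%g) degenerate (Var~0); dropped", d, r
                )
                dropped.append((d, r))
                continue
            p = pearson3_pvalue(T, E1, Var, g)
            base.append(
                BaseTestResult(d=d, r=r, T=T, E1=E1, Var=Var, E3=E3,
                               gamma=g, pvalue=p)
            )
    if not base:
        raise DegenerateNullError("every base test degenerated")
    T_ens, P = cauchy_combine([b.pvalue for b in base])
    return EnsembleResult(base=base, T_ens=T_ens, P=P, D_set=D_set,
                          R_set=R_set, dropped=dropped)
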