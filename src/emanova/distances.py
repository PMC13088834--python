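"""Pairwise beta-diversity distances: UniFrac (weighted/unweighted), Bray-Curtis.

Weighted UniFrac follows the generalized form with abundance exponent
``alpha`` (default 0.5):

    d_ij = sum_l b_l (p_il + p_jl)^alpha |p_il - p_jl|
           / sum_l b_l (p_il + p_jl)^alpha

where ``p_il`` is the total relative abundance of the leaves below branch
``l`` in sample ``i`` and ``b_l`` the branch length.  Branches absent from
both samples (p_il + p_jl = 0) drop out of numerator and denominator.
Unweighted UniFrac compares presence/absence only, normalized by the *total*
tree length:

    d_ij = sum_l b_l |I(p_il > 0) - I(p_jl > 0)| / sum_l b_l.

Bray-Curtis is ``sum_k |p_ik - p_jk| / sum_k (p_ik + p_jk)``, which equals
half the L1 distance between compositional rows.

Metric ids follow the convention d=1 weighted UniFrac, d=2 unweighted
UniFrac, d=3 Bray-Curtis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_formats import AbundanceTable, AlignmentError, PhyloTree

__all__ = [
    "DistanceMatrix",
    "BranchProfile",
    "branch_profile",
    "weighted_unifrac",
    "unweighted_unifrac",
    "bray_curtis",
    "METRIC_NAMES",
]

METRIC_NAMES = {1: "weighted_unifrac", 2: "unweighted_unifrac", 3: "bray_curtis"}


@dataclass
class DistanceMatrix:
    """Symmetric n x n distance matrix with a metric identifier."""

    values: np.ndarray
    metric_id: int
    sample_ids: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = 0.5 * (v + v.T)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        ).to_csv(path, sep="\t", float_format="%.17g", index_label="sample_id")


@dataclass
class BranchProfile:
    """Per-sample descendant-abundance profile over the tree's branches.

    ``proportions[i, l]`` is the summed relative abundance in sample ``i`` of
    all leaves below branch ``l``; branches are enumerated in deterministic
    postorder, root excluded.
    """

    proportions: np.ndarray
    lengths: np.ndarray
    sample_ids: list[str]


def branch_profile(table: AbundanceTable, tree: PhyloTree) -> BranchProfile:
    """Accumulate leaf abundances up the tree (postorder, root-exclusive)."""
    col = {otu: k for k, otu in enumerate(table.otu_ids)}
    missing = [o for o in table.otu_ids if o not in set(tree.leaf_labels)]
    if missing:
        raise AlignmentError(
            f"{len(missing)} OTU(s) not found as tree leaves, e.g. {missing[:5]}"
        )
    n = table.n_samples
    profiles: list[np.ndarray] = []
    lengths: list[float] = []
    acc: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder(include_self=False):
        if node.is_tip():
            # leaves not present in the table carry zero abundance
            k = col.get(node.name)
            p = table.values[:, k].copy() if k is not None else np.zeros(n)
        else:
            p = np.zeros(n)
            for child in node.children:
                p += acc.pop(id(child))
        acc[id(node)] = p
        profiles.append(p)
        lengths.append(float(node.length))
    return BranchProfile(
        np.column_stack(profiles), np.asarray(lengths), list(table.sample_ids)
    )


def weighted_unifrac(profile: BranchProfile, alpha: float = 0.5) -> DistanceMatrix:
    """Generalized weighted UniFrac with abundance exponent ``alpha`` in [0, 1]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    P = profile.proportions
    b = profile.lengths
    n = P.shape[0]
    D = np.zeros((n, n))
    degenerate = False
    for i in range(n - 1):
        s = P[i] + P[i + 1 :]  # (n-i-1, L)
        diff = np.abs(P[i] - P[i + 1 :])
        active = s > 0
        # 0^alpha * 0 = 0 convention: inactive branches contribute nothing
        # (the dummy base 1.0 sidesteps 0**0 at alpha=0)
        w = np.where(active, b[None, :] * np.where(active, s, 1.0) ** alpha, 0.0)
        num = (w * diff).sum(axis=1)
        den = w.sum(axis=1)
        zero = den == 0
        if zero.any():
            degenerate = True
            den[zero] = 1.0
            num[zero] = 0.0
        D[i, i + 1 :] = num / den
    if degenerate:
        warnings.warn(
            "sample pair(s) with no shared nonzero branches; distance set to 0",
            stacklevel=2,
        )
    return DistanceMatrix(D + D.T, 1, profile.sample_ids)


def unweighted_unifrac(profile: BranchProfile) -> DistanceMatrix:
    """Presence/absence UniFrac normalized by total tree length."""
    total = float(profile.lengths.sum())
    if total <= 0:
        raise ValueError("total tree length is 0")
    pres = (profile.proportions > 0).astype(float)
    weighted = pres * profile.lengths
    c = weighted.sum(axis=1)
    inner = weighted @ pres.T
    D = (c[:, None] + c[None, :] - inner - inner.T) / total
    return DistanceMatrix(D, 2, profile.sample_ids)


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between compositional rows."""
    D = squareform(pdist(table.values, metric="braycurtis"))
    return DistanceMatrix(D, 3, list(table.sample_ids))
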