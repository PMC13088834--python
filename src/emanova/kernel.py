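"""Distance -> centered, PSD-repaired, powered kernels.

Pipeline: ``S = -d^2/2`` (Gower similarity), ``K = H S H`` with
``H = I - 11'/n`` (double centering), eigendecomposition ``K = U L U'``,
PSD repair ``K* = U |L| U'``, and spectral powering
``(K*)^r = U |L|^r U'`` for each exponent ``r > 0``.

Microbiome distances (UniFrac, Bray-Curtis) are not Euclidean-embeddable in
general, so ``K`` routinely has negative eigenvalues; the absolute-value
repair keeps the spectrum's magnitudes while forcing positive
semi-definiteness, and powering then reweights the spectrum: small ``r``
flattens it (up-weighting minor axes of variation), large ``r`` concentrates
on the dominant axes.  Because ``|0| = 0``, the all-ones null vector of the
centered kernel survives repair and powering: every ``(K*)^r`` is itself
double-centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "CenteredKernel",
    "similarity_from_distance",
    "gower_center",
    "psd_fix",
    "kernel_power",
    "centered_kernel",
]

#: eigenvalues below this times max |eigenvalue| are zeroed before powering
#: (r < 1 would otherwise amplify numerical noise)
EIG_RTOL = 1e-12


def similarity_from_distance(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower similarity ``s_ij = -d_ij^2 / 2``."""
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    return -0.5 * d * d


def gower_center(S: np.ndarray) -> np.ndarray:
    """Double-center a similarity matrix: ``K = H S H``."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to center")
    if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
        raise ValueError("similarity matrix must be symmetric")
    row = S.mean(axis=1)
    K = S - row[:, None] - row[None, :] + row.mean()
    return 0.5 * (K + K.T)


def psd_fix(K: np.ndarray) -> np.ndarray:
    """PSD repair ``K* = U |Lambda| U'`` via symmetric eigendecomposition."""
    eigvals, U = np.linalg.eigh(np.asarray(K, dtype=float))
    lam = _clean_spectrum(eigvals)
    return (U * np.abs(lam)) @ U.T


def kernel_power(Kstar: np.ndarray, r: float) -> np.ndarray:
    """Spectral power ``(K*)^r`` with the convention ``0^r = 0``."""
    if r <= 0:
        raise ValueError("exponent r must be positive")
    eigvals, U = np.linalg.eigh(np.asarray(Kstar, dtype=float))
    lam = np.abs(_clean_spectrum(eigvals))
    return (U * lam**r) @ U.T


def _clean_spectrum(eigvals: np.ndarray) -> np.ndarray:
    scale = np.abs(eigvals).max()
    if scale == 0:
        return eigvals
    out = eigvals.copy()
    out[np.abs(out) < EIG_RTOL * scale] = 0.0
    return out


@dataclass
class CenteredKernel:
    """Centered kernel of one distance matrix with its spectrum and powers.

    A single eigendecomposition serves every requested exponent, so all
    powers share one set of eigenvectors and are mutually consistent.
    """

    S: np.ndarray
    K: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    metric_id: int | None = None
    _powers: dict[float, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.K.shape[0]

    @property
    def abs_eigvals(self) -> np.ndarray:
        return np.abs(self.eigvals)

    @property
    def kstar(self) -> np.ndarray:
        return self.power(1.0)

    def power(self, r: float) -> np.ndarray:
        """``(K*)^r = U |Lambda|^r U'`` (cached per exponent)."""
        if r <= 0:
            raise ValueError("exponent r must be positive")
        r = float(r)
        if r not in self._powers:
            lam = self.abs_eigvals**r
            self._powers[r] = (self.eigvecs * lam) @ self.eigvecs.T
        return self._powers[r]

    def has_negative_eigenvalues(self, rtol: float = 1e-8) -> bool:
        return bool((self.eigvals < -rtol * self.abs_eigvals.max()).any())


def centered_kernel(D: DistanceMatrix | np.ndarray) -> CenteredKernel:
    """Full chain distance -> similarity -> centered kernel -> spectrum."""
    S = similarity_from_distance(D)
    K = gower_center(S)
    eigvals, U = np.linalg.eigh(K)
    metric = D.metric_id if isinstance(D, DistanceMatrix) else None
    return CenteredKernel(S, K, _clean_spectrum(eigvals), U, metric)
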