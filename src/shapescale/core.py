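"""Shape-complexity mathematics.

The shape complexity (SC) of a set of samples is

    SC = g * h,   g = (sum_{i<j} r_ij^2)^(1/2),   h = sum_{i<j} 1/r_ij,

where r_ij is the Euclidean distance between samples i and j after each
dimension k has been standardized by its sample standard deviation sigma_k
and stretched by a positive scaling factor alpha_k:

    r_ij^2 = sum_k alpha_k^2 rho_ijk^2,   rho_ijk = (X_ik - X_jk) / sigma_k.

g grows fastest when the *largest* distances grow, h shrinks fastest when
the *smallest* distances grow, so SC embodies a tension between the two
ends of the pair-distance distribution.  SC is radially invariant: it has
the same value at alpha and at t*alpha for any t > 0, equivalently
sum_k alpha_k * dSC/dalpha_k = 0.

All pair quantities are computed over the unique rows only (SC is undefined
when two samples coincide), while sigma_k is computed over all n_orig rows
so that sigma_k^2 * n_orig*(n_orig-1) equals the sum of squared pair
differences over the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

#: Relaxed positivity bound for scaling factors (division-by-zero guard).
ALPHA_MIN = 1e-5

#: Tolerance on the sphere constraint |sum alpha_k^2 - d|.
SPHERE_TOL = 1e-8


class ConstantColumnError(ValueError):
    """A dimension has zero sample standard deviation."""


class DuplicatePairError(ValueError):
    """A pair distance is zero; duplicate rows must be removed first."""


def _as_alpha(factors) -> np.ndarray:
    """Coerce ScalingFactors or array_like to a 1-D positive float vector."""
    if isinstance(factors, ScalingFactors):
        return factors.alpha
    alpha = np.asarray(factors, dtype=float).ravel()
    if alpha.size == 0 or np.any(~np.isfinite(alpha)) or np.any(alpha <= 0):
        raise ValueError("scaling factors must be finite and strictly positive")
    return alpha


@dataclass(frozen=True)
class ScalingFactors:
    """Per-dimension scaling factors alpha_k, optionally on the radius-sqrt(d) sphere.

    Parameters
    ----------
    alpha : ndarray
        Positive factors, one per dimension.  Each must satisfy
        ``alpha_k >= ALPHA_MIN`` (the relaxed positivity constraint used
        throughout the optimization).
    on_sphere : bool
        If True, ``sum(alpha**2)`` must equal the dimension count d to
        within ``SPHERE_TOL``.
    """

    alpha: np.ndarray
    on_sphere: bool = False

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float).ravel()
        object.__setattr__(self, "alpha", alpha)
        if alpha.size == 0 or np.any(~np.isfinite(alpha)):
            raise ValueError("alpha must be a non-empty finite vector")
        if np.any(alpha < ALPHA_MIN - 1e-12):
            raise ValueError(f"alpha components must be >= {ALPHA_MIN}")
        if self.on_sphere:
            resid = abs(float(alpha @ alpha) - alpha.size)
            if resid > SPHERE_TOL:
                raise ValueError(
                    f"alpha flagged on-sphere but |sum(alpha^2) - d| = {resid:.3g}"
                )

    @property
    def d(self) -> int:
        return self.alpha.size

    def projected_to_sphere(self) -> "ScalingFactors":
        """Rescale onto the radius-sqrt(d) sphere (a no-op for SC by radial invariance)."""
        t = np.sqrt(self.d / float(self.alpha @ self.alpha))
        return ScalingFactors(self.alpha * t, on_sphere=True)


@dataclass(frozen=True)
class DataMatrix:
    """An n_orig x d sample matrix with scaling bookkeeping.

    Attributes
    ----------
    values : ndarray, shape (n_orig, d)
        The raw samples, duplicates included.
    sigma : ndarray, shape (d,)
        Per-dimension sample standard deviation over *all* n_orig rows
        (denominator n_orig - 1).
    unique_index : ndarray
        Row indices (ascending) of the n duplicate-free rows; pair sums and
        SC are computed over these rows only.
    """

    values: np.ndarray
    sigma: np.ndarray = field(repr=False)
    unique_index: np.ndarray = field(repr=False)

    @classmethod
    def from_array(cls, values) -> "DataMatrix":
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expected a 2-D sample-by-dimension matrix")
        n_orig, d = values.shape
        if n_orig < 2 or d < 2:
            raise ValueError("need at least 2 samples and 2 dimensions")
        if not np.all(np.isfinite(values)):
            raise ValueError("data matrix contains non-finite entries")
        sigma = values.std(axis=0, ddof=1)
        for k, s in enumerate(sigma):
            if s <= 0:
                raise ConstantColumnError(
                    f"dimension {k + 1} is constant (sigma_k = 0); "
                    "remove it before computing shape complexity"
                )
        _, uidx = np.unique(values, axis=0, return_index=True)
        unique_index = np.sort(uidx)
        if unique_index.size < 2:
            raise ValueError("fewer than 2 unique rows after duplicate removal")
        return cls(values=values, sigma=sigma, unique_index=unique_index)

    @property
    def n_orig(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def n(self) -> int:
        """Number of unique rows."""
        return self.unique_index.size

    @property
    def N(self) -> int:
        """The pair-sum constant n_orig * (n_orig - 1)."""
        return self.n_orig * (self.n_orig - 1)

    def unique_values(self) -> np.ndarray:
        return self.values[self.unique_index]


class SCValue(NamedTuple):
    sc: float
    g: float
    h: float


@dataclass(frozen=True)
class PairwiseBundle:
    """All per-pair and aggregate SC quantities at a given alpha.

    ``rho2`` holds the standardized squared pair differences rho_ijk^2 for
    the n(n-1)/2 unordered unique-row pairs in lexicographic (i < j) order;
    ``r`` the scaled pair distances; ``gk``/``hk`` the gradient components
    of g and h; ``grad`` the SC gradient  g'_k h + g h'_k.
    """

    rho2: np.ndarray
    alpha: np.ndarray
    r: np.ndarray
    g: float
    h: float
    sc: float
    gk: np.ndarray
    hk: np.ndarray
    grad: np.ndarray


def standardized_sq_diffs(data: DataMatrix) -> np.ndarray:
    """Standardized squared pair differences rho_ijk^2 over the unique rows.

    Returns an (n_pairs, d) array, pairs in lexicographic (i < j) order.
    sigma_k is the one stored on ``data`` (computed over all n_orig rows).
    """
    u = data.unique_values()
    i, j = np.triu_indices(u.shape[0], k=1)
    rho = (u[i] - u[j]) / data.sigma
    return rho * rho


def pair_distances(rho2: np.ndarray, factors) -> np.ndarray:
    """Scaled pair distances r_ij = sqrt(sum_k alpha_k^2 rho_ijk^2)."""
    alpha = _as_alpha(factors)
    if rho2.shape[1] != alpha.size:
        raise ValueError("rho2 and alpha dimension counts disagree")
    r = np.sqrt(rho2 @ (alpha * alpha))
    if np.any(r <= 0.0):
        raise DuplicatePairError(
            "zero pair distance encountered; remove duplicate rows before "
            "computing shape complexity"
        )
    return r


def shape_complexity(rho2: np.ndarray, factors) -> SCValue:
    """SC = g*h with g the root-sum-square of pair distances, h the sum of inverses."""
    r = pair_distances(rho2, factors)
    g = float(np.sqrt(r @ r))
    h = float(np.sum(1.0 / r))
    return SCValue(sc=g * h, g=g, h=h)


def gh_gradients(rho2: np.ndarray, factors) -> tuple[np.ndarray, np.ndarray]:
    """Gradient components g'_k and h'_k of the two SC factors.

    g'_k = alpha_k g^-1 sum_{i<j} rho_ijk^2
    h'_k = -alpha_k sum_{i<j} r_ij^-3 rho_ijk^2
    """
    alpha = _as_alpha(factors)
    r = pair_distances(rho2, alpha)
    g = np.sqrt(r @ r)
    gk = alpha / g * rho2.sum(axis=0)
    hk = -alpha * (rho2.T @ (r ** -3))
    return gk, hk


def sc_gradient(rho2: np.ndarray, factors) -> np.ndarray:
    """Gradient of SC: SC'_k = g'_k h + g h'_k."""
    alpha = _as_alpha(factors)
    sc = shape_complexity(rho2, alpha)
    gk, hk = gh_gradients(rho2, alpha)
    return gk * sc.h + sc.g * hk


def pairwise_bundle(rho2: np.ndarray, factors) -> PairwiseBundle:
    """Assemble every SC quantity at alpha in one pass."""
    alpha = _as_alpha(factors)
    r = pair_distances(rho2, alpha)
    g = float(np.sqrt(r @ r))
    h = float(np.sum(1.0 / r))
    gk = alpha / g * rho2.sum(axis=0)
    hk = -alpha * (rho2.T @ (r ** -3))
    return PairwiseBundle(
        rho2=rho2, alpha=alpha, r=r, g=g, h=h, sc=g * h,
        gk=gk, hk=hk, grad=gk * h + g * hk,
    )


def g_closed_form(data: DataMatrix, factors) -> float:
    """Closed form g = sqrt(N * sum_k alpha_k^2), exact on duplicate-free data.

    Relies on the pair-sum identity sum_{i<j} rho_ijk^2 = N, which holds
    exactly only when every row of the matrix is unique (n == n_orig).
    """
    alpha = _as_alpha(factors)
    if alpha.size != data.d:
        raise ValueError("alpha dimension count disagrees with data")
    return float(np.sqrt(data.N * (alpha @ alpha)))
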