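"""Synthetic fixtures and benchmark preparation.

The mixture generator emulates the situation the scaling method targets:
well-formed Gaussian clusters plus dimensions carrying no cluster signal
whose raw scale is large, so that dividing by the standard deviation
promotes pure noise to the same footing as informative dimensions.  The
benchmark helpers reproduce the corrected Iris table, the DR3 reduction
(centered, unscaled PCA, first three components) and the 10-column
truncation used for the diagnostic breast-cancer table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .core import DataMatrix

logger = logging.getLogger(__name__)

# UCI rows that the original flower measurements correct (1-based rows 35, 38).
_UCI_ROW_35 = np.array([4.9, 3.1, 1.5, 0.1])
_UCI_ROW_38 = np.array([4.9, 3.1, 1.5, 0.1])
_FIXED_ROW_35 = np.array([4.9, 3.1, 1.5, 0.2])
_FIXED_ROW_38 = np.array([4.9, 3.6, 1.4, 0.1])


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian mixture with optional pure-noise dimensions and duplicates.

    Defaults are the package's standard noise-dimension fixture: three
    unit-scale clusters of 40 samples at (0,0), (4,0), (0,4) plus one
    noise dimension of scale 100 — large enough that 1/sigma scaling
    turns it into full-strength noise relative to the signal dimensions.
    """

    n_per_cluster: tuple[int, ...] = (40, 40, 40)
    means: tuple[tuple[float, ...], ...] = ((0.0, 0.0), (4.0, 0.0), (0.0, 4.0))
    scales: float | tuple = 1.0
    n_noise_dims: int = 1
    noise_scale: float = 100.0
    duplicate_count: int = 0
    seed: int | None = None

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        if means.ndim != 2 or len(self.n_per_cluster) != means.shape[0]:
            raise ValueError("means must be one d-vector per cluster")
        if any(n < 1 for n in self.n_per_cluster):
            raise ValueError("each cluster needs at least one sample")
        if sum(self.n_per_cluster) < 4:
            raise ValueError("total sample count must be >= 4")
        scales = np.broadcast_to(np.asarray(self.scales, dtype=float),
                                 means.shape)
        if np.any(scales <= 0) or self.noise_scale <= 0:
            raise ValueError("all scales must be > 0")
        if self.n_noise_dims < 0 or self.duplicate_count < 0:
            raise ValueError("counts must be non-negative")


def make_mixture(spec: MixtureSpec) -> tuple[DataMatrix, np.ndarray]:
    """Draw the mixture; returns (DataMatrix, reference labels).

    Noise dimensions are appended after the signal dimensions and carry
    no cluster structure.  Duplicates are injected by copying rows chosen
    at random (labels copied along), so exact-duplicate removal recovers
    the original rows.
    """
    rng = np.random.default_rng(spec.seed)
    means = np.asarray(spec.means, dtype=float)
    scales = np.broadcast_to(np.asarray(spec.scales, dtype=float), means.shape)
    blocks, labels = [], []
    for c, n_c in enumerate(spec.n_per_cluster):
        blocks.append(rng.normal(means[c], scales[c], size=(n_c, means.shape[1])))
        labels.append(np.full(n_c, c))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    if spec.n_noise_dims:
        noise = rng.normal(0.0, spec.noise_scale,
                           size=(X.shape[0], spec.n_noise_dims))
        X = np.hstack([X, noise])
    if spec.duplicate_count:
        idx = rng.choice(X.shape[0], size=spec.duplicate_count, replace=True)
        X = np.vstack([X, X[idx]])
        y = np.concatenate([y, y[idx]])
    return DataMatrix.from_array(X), y


def noise_dimension_fixture(seed: int | None = None
                            ) -> tuple[DataMatrix, np.ndarray]:
    """The default fixture used by the sweep self-test (see MixtureSpec)."""
    return make_mixture(MixtureSpec(seed=seed))


def corrected_iris(raw: np.ndarray | None = None
                   ) -> tuple[DataMatrix, np.ndarray]:
    """The 150 x 4 Iris matrix with the two flower-measurement corrections.

    Row 35 (1-based) should read 4.9 3.1 1.5 0.2 and row 38 should read
    4.9 3.6 1.4 0.1.  Distributions of the table differ: the raw UCI file
    carries the erroneous rows while others (including scikit-learn's
    bundled copy) are already corrected.  Each row is corrected only if it
    matches the known erroneous values; any third variant draws a warning.
    """
    if raw is None:
        from sklearn.datasets import load_iris

        raw, labels = load_iris(return_X_y=True)
    else:
        labels = None
    X = np.asarray(raw, dtype=float).copy()
    if X.shape != (150, 4):
        raise ValueError(f"expected a 150x4 table, got {X.shape}")
    for idx, bad, fixed in ((34, _UCI_ROW_35, _FIXED_ROW_35),
                            (37, _UCI_ROW_38, _FIXED_ROW_38)):
        if np.allclose(X[idx], bad):
            X[idx] = fixed
        elif not np.allclose(X[idx], fixed):
            warnings.warn(
                f"row {idx + 1} matches neither the UCI nor the corrected "
                "values; leaving it unchanged", stacklevel=2)
    if labels is None:
        labels = np.repeat([0, 1, 2], 50)
    return DataMatrix.from_array(X), np.asarray(labels)


def dr3_reduce(values, n_components: int = 3
               ) -> tuple[np.ndarray, float]:
    """Centered (not scaled) PCA scores, first ``n_components`` components.

    Returns (scores, retained variance fraction).  Component signs follow
    the convention that the loading of largest magnitude is positive, so
    the output does not depend on solver sign choices or row order.
    """
    X = np.asarray(values, dtype=float)
    if X.shape[1] < n_components:
        raise ValueError("fewer input dimensions than requested components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)  # centers, does not scale
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < n_components:
        raise ValueError("data rank is below the requested component count")
    flip = np.sign(pca.components_[
        np.arange(n_components),
        np.argmax(np.abs(pca.components_), axis=1),
    ])
    scores = scores * flip
    retained = float(pca.explained_variance_ratio_.sum())
    return scores, retained


def truncate_means_10(values) -> np.ndarray:
    """First 10 of the 30 image-statistic dimensions (the mean-value block)."""
    X = np.asarray(values, dtype=float)
    if X.shape[1] != 30:
        raise ValueError(f"expected 30 columns, got {X.shape[1]}")
    return X[:, :10].copy()


def simple_impute(values) -> np.ndarray:
    """Per-column mean imputation of NaN entries.

    A deliberately plain imputer.  If imputation makes two rows collide,
    a jitter of 1e-9 is added to the later row's imputed entries (logged),
    so the imputed matrix never gains new duplicates.
    """
    X = np.asarray(values, dtype=float).copy()
    mask = np.isnan(X)
    if np.any(mask.all(axis=0)):
        raise ValueError("a column is entirely missing; cannot impute")
    col_means = np.nanmean(X, axis=0)
    X[mask] = np.take(col_means, np.nonzero(mask)[1])

    imputed_rows = np.nonzero(mask.any(axis=1))[0]
    seen = {tuple(row) for i, row in enumerate(X) if i not in set(imputed_rows)}
    for i in imputed_rows:
        while tuple(X[i]) in seen:
            X[i, mask[i]] += 1e-9
            logger.info("imputation collision on row %d; jitter applied", i)
        seen.add(tuple(X[i]))
    return X
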