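"""End-to-end workflow: scale, cluster with k-means, evaluate, sweep trials.

Scaling schemes mirror the three in-scope preprocessing choices: leave the
data alone, divide each dimension by its standard deviation, or multiply
by alpha_k / sigma_k with alpha_k from an optimization trial.  Clustering
is Lloyd k-means with k-means++ initialization, stabilized by restarts
(best of ``restarts`` runs by the k-means objective) so results are
reproducible without reference to any particular RNG stream.  Evaluation
uses all n_orig samples, duplicates included; only the SC/optimization
machinery works on the unique rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .core import DataMatrix, _as_alpha
from .metrics import ami_max, ari_fnc, PartitionPair
from .optimize import (
    Mode,
    TrialConfig,
    TrialResult,
    discard_fraction,
    run_trials,
)

SchemeKind = Literal["none", "inv_sigma", "alpha_over_sigma"]


class EmptyClusterError(RuntimeError):
    """k-means persistently returned fewer than C non-empty clusters."""


@dataclass(frozen=True)
class ScalingScheme:
    """One of the three per-dimension scaling choices."""

    kind: SchemeKind
    alpha: np.ndarray | None = None

    def __post_init__(self):
        if self.kind == "alpha_over_sigma":
            if self.alpha is None:
                raise ValueError("alpha_over_sigma requires alpha")
            object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        elif self.alpha is not None:
            raise ValueError(f"scheme {self.kind!r} takes no alpha")

    @classmethod
    def none(cls) -> "ScalingScheme":
        return cls("none")

    @classmethod
    def inv_sigma(cls) -> "ScalingScheme":
        return cls("inv_sigma")

    @classmethod
    def alpha_over_sigma(cls, alpha) -> "ScalingScheme":
        return cls("alpha_over_sigma", alpha=np.asarray(alpha, dtype=float))


def dedup(values) -> DataMatrix:
    """Build a DataMatrix with exact-duplicate bookkeeping.

    The original rows are all retained (sigma and evaluation use them);
    unique_index marks the duplicate-free subset used by SC.
    """
    return DataMatrix.from_array(values)


def column_factors(data: DataMatrix, scheme: ScalingScheme) -> np.ndarray:
    """The multiplicative factor applied to each column under ``scheme``."""
    if scheme.kind == "none":
        return np.ones(data.d)
    if scheme.kind == "inv_sigma":
        return 1.0 / data.sigma
    if scheme.alpha.size != data.d:
        raise ValueError("alpha dimension count disagrees with data")
    return scheme.alpha / data.sigma


def apply_scaling(data: DataMatrix, scheme: ScalingScheme) -> np.ndarray:
    """Scaled copy of the full n_orig x d matrix."""
    return data.values * column_factors(data, scheme)


def cluster_kmeans(scaled: np.ndarray, C: int, seed: int | None = 0,
                   restarts: int = 20, max_reseeds: int = 10) -> np.ndarray:
    """Restart-stabilized Lloyd k-means returning exactly C non-empty clusters.

    Should a run come back with an empty cluster (the fnc premise of the
    evaluation indices would be violated), it is re-seeded up to
    ``max_reseeds`` times before giving up.
    """
    if C < 2:
        raise ValueError("C must be >= 2")
    base = 0 if seed is None else int(seed)
    for attempt in range(max_reseeds + 1):
        km = KMeans(n_clusters=C, n_init=restarts,
                    random_state=(base + 7919 * attempt) % 2**32)
        labels = km.fit_predict(scaled)
        if np.unique(labels).size == C:
            return labels
    raise EmptyClusterError(
        f"k-means returned fewer than {C} non-empty clusters "
        f"after {max_reseeds + 1} seedings"
    )


def evaluate_run(obtained, reference) -> tuple[float, float]:
    """(ARI_fnc, AMI_max) of an obtained labeling against the reference."""
    pp = PartitionPair.from_labels(reference, obtained)
    return ari_fnc(pp), ami_max(pp)


@dataclass
class BenchmarkRun:
    """A full multi-start sweep with per-trial clustering evaluation.

    ``trials`` is a tidy frame with one row per trial: the initial and
    converged factors, objective, convergence flag and both indices
    (NaN for discarded trials).  ``best_alpha`` is the converged alpha
    achieving the highest ARI_fnc.
    """

    dataset: str
    mode: Mode
    n_clusters: int
    seed: int | None
    trials: pd.DataFrame
    discard_fraction: float

    @property
    def evaluated(self) -> pd.DataFrame:
        return self.trials[self.trials["converged"]]

    def interval(self, index: str = "ari_fnc") -> tuple[float, float]:
        vals = self.evaluated[index]
        return float(vals.min()), float(vals.max())

    @property
    def best_alpha(self) -> np.ndarray:
        ev = self.evaluated
        row = ev.loc[ev["ari_fnc"].idxmax()]
        d = sum(c.startswith("alpha_") for c in self.trials.columns)
        return row[[f"alpha_{k + 1}" for k in range(d)]].to_numpy(dtype=float)

    def summary(self) -> dict:
        lo, hi = self.interval("ari_fnc")
        lo2, hi2 = self.interval("ami_max")
        return {
            "dataset": self.dataset,
            "mode": self.mode,
            "n_trials": int(len(self.trials)),
            "discard_fraction": self.discard_fraction,
            "ari_fnc_min": lo, "ari_fnc_max": hi,
            "ami_max_min": lo2, "ami_max_max": hi2,
            "best_alpha": [float(a) for a in self.best_alpha],
        }

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def trial_sweep(data: DataMatrix, reference, C: int, n_trials: int,
                seed: int | None = None, mode: Mode = "problem_p",
                config: TrialConfig | None = None,
                dataset: str = "", kmeans_restarts: int = 20,
                kmeans_seed: int | None = None) -> BenchmarkRun:
    """Solve, scale, cluster and evaluate for every trial.

    The k-means seed is fixed across trials (derived from the master seed
    unless given), so differences between trials reflect only the scaling
    factors.  Raises if every trial failed to converge.
    """
    reference = np.asarray(reference).ravel()
    trials = run_trials(data, n_trials=n_trials, seed=seed, mode=mode,
                        config=config)
    if all(not t.converged for t in trials):
        raise RuntimeError("all optimization trials failed to converge")
    if kmeans_seed is None:
        kmeans_seed = 0 if seed is None else int(seed) % 2**31

    rows = []
    for t in trials:
        rec = {"trial_id": t.trial_id,
               **{f"alpha_{k + 1}": t.alpha[k] for k in range(data.d)},
               "objective": t.objective, "converged": t.converged,
               "ari_fnc": np.nan, "ami_max": np.nan}
        if t.converged:
            scaled = apply_scaling(
                data, ScalingScheme.alpha_over_sigma(t.alpha))
            labels = cluster_kmeans(scaled, C, seed=kmeans_seed,
                                    restarts=kmeans_restarts)
            rec["ari_fnc"], rec["ami_max"] = evaluate_run(labels, reference)
        rows.append(rec)
    frame = pd.DataFrame(rows)
    return BenchmarkRun(
        dataset=dataset, mode=mode, n_clusters=C, seed=seed, trials=frame,
        discard_fraction=discard_fraction(trials),
    )


def distance_histogram(scaled: np.ndarray, bins=50,
                       bin_width: float | None = None,
                       hist_range: tuple[float, float] | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of all unique-pair Euclidean distances of a scaled matrix.

    Passing ``bin_width`` (with an optional shared ``hist_range``) gives
    fixed absolute-width bins so histograms of differently scaled versions
    of one data set are directly comparable.
    """
    r = pdist(np.asarray(scaled, dtype=float))
    if bin_width is not None:
        lo, hi = hist_range if hist_range is not None else (0.0, float(r.max()))
        edges = np.arange(lo, hi + bin_width, bin_width)
        return np.histogram(r, bins=edges)
    return np.histogram(r, bins=bins, range=hist_range)


def plot_distance_histograms(data: DataMatrix, schemes: dict[str, ScalingScheme],
                             bins: int = 60, ax=None):
    """Overlay pair-distance histograms for several scaling schemes.

    Bins have one fixed absolute width shared by all schemes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rmax = max(float(pdist(apply_scaling(data, s)).max())
               for s in schemes.values())
    width = rmax / bins
    for name, scheme in schemes.items():
        counts, edges = distance_histogram(
            apply_scaling(data, scheme), bin_width=width, hist_range=(0.0, rmax))
        ax.stairs(counts, edges, label=name)
    ax.set_xlabel("pair distance r_ij")
    ax.set_ylabel("pair count")
    ax.legend()
    return ax


def load_matrix(path, delimiter=",", header: bool = False) -> np.ndarray:
    """Numeric sample-by-dimension matrix from delimited text."""
    frame = pd.read_csv(path, delimiter=delimiter,
                        header=0 if header else None)
    return frame.to_numpy(dtype=float)


def load_labels(path) -> np.ndarray:
    """Integer labels, one per line."""
    return np.loadtxt(path, dtype=int).ravel()
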