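"""Model/Results interface over the scaling-factor machinery.

``ShapeComplexityScaling`` is constructed from a sample-by-dimension
matrix (optionally with a reference partition) and ``fit`` runs the
multi-start optimization, returning a ``ScalingResults`` object that
carries the per-trial estimates, the clustering evaluation of each
converged trial, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataMatrix, shape_complexity, sc_gradient, standardized_sq_diffs
from .optimize import Mode, TrialConfig
from .pipeline import (
    BenchmarkRun,
    ScalingScheme,
    apply_scaling,
    cluster_kmeans,
    evaluate_run,
    trial_sweep,
)


class ShapeComplexityScaling:
    """Estimate per-dimension scaling factors for distance-based clustering.

    Parameters
    ----------
    endog : array_like, shape (n_orig, d)
        The samples to be clustered.  Duplicate rows are kept for scaling
        and evaluation but excluded from the shape-complexity sums.
    reference : array_like, optional
        Reference labels; when given, every converged trial is also
        clustered with k-means and scored with ARI_fnc / AMI_max.
    n_clusters : int, optional
        Cluster count C for k-means; defaults to the number of distinct
        reference labels.

    Examples
    --------
    >>> model = ShapeComplexityScaling(X, reference=y)
    >>> res = model.fit(n_trials=1000, seed=7)
    >>> print(res.summary())
    """

    def __init__(self, endog, reference=None, n_clusters: int | None = None,
                 dataset: str = ""):
        self.data = endog if isinstance(endog, DataMatrix) \
            else DataMatrix.from_array(endog)
        self.reference = None if reference is None \
            else np.asarray(reference).ravel()
        if self.reference is not None and self.reference.size != self.data.n_orig:
            raise ValueError("reference length must equal the sample count")
        if n_clusters is None and self.reference is not None:
            n_clusters = int(np.unique(self.reference).size)
        self.n_clusters = n_clusters
        self.dataset = dataset
        self._rho2 = None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str | None = None,
                       n_clusters: int | None = None) -> "ShapeComplexityScaling":
        reference = None
        if label_col is not None:
            reference = frame[label_col].to_numpy()
            frame = frame.drop(columns=[label_col])
        return cls(frame.to_numpy(dtype=float), reference=reference,
                   n_clusters=n_clusters)

    @property
    def rho2(self) -> np.ndarray:
        if self._rho2 is None:
            self._rho2 = standardized_sq_diffs(self.data)
        return self._rho2

    def sc(self, alpha) -> float:
        """Shape complexity of the data at the given factors."""
        return shape_complexity(self.rho2, alpha).sc

    def sc_gradient(self, alpha) -> np.ndarray:
        return sc_gradient(self.rho2, alpha)

    def fit(self, n_trials: int = 1000, seed: int | None = None,
            mode: Mode = "problem_p", config: TrialConfig | None = None,
            kmeans_restarts: int = 20) -> "ScalingResults":
        """Run the multi-start protocol (and per-trial evaluation if labelled)."""
        if self.reference is None or self.n_clusters is None:
            from .optimize import run_trials, discard_fraction

            trials = run_trials(self.data, n_trials=n_trials, seed=seed,
                                mode=mode, config=config)
            rows = [{"trial_id": t.trial_id,
                     **{f"alpha_{k + 1}": t.alpha[k] for k in range(self.data.d)},
                     "objective": t.objective, "converged": t.converged}
                    for t in trials]
            run = BenchmarkRun(dataset=self.dataset, mode=mode,
                               n_clusters=0, seed=seed,
                               trials=pd.DataFrame(rows),
                               discard_fraction=discard_fraction(trials))
        else:
            run = trial_sweep(self.data, self.reference, C=self.n_clusters,
                              n_trials=n_trials, seed=seed, mode=mode,
                              config=config, dataset=self.dataset,
                              kmeans_restarts=kmeans_restarts)
        return ScalingResults(model=self, run=run)


@dataclass
class ScalingResults:
    """Fitted scaling factors plus per-trial diagnostics."""

    model: ShapeComplexityScaling
    run: BenchmarkRun

    @property
    def trials(self) -> pd.DataFrame:
        return self.run.trials

    @property
    def n_converged(self) -> int:
        return int(self.run.trials["converged"].sum())

    @property
    def discard_fraction(self) -> float:
        return self.run.discard_fraction

    @property
    def params(self) -> np.ndarray:
        """Selected alpha: highest ARI_fnc when evaluated, else lowest objective."""
        frame = self.run.trials
        conv = frame[frame["converged"]]
        d = self.model.data.d
        cols = [f"alpha_{k + 1}" for k in range(d)]
        if "ari_fnc" in frame.columns and conv["ari_fnc"].notna().any():
            row = conv.loc[conv["ari_fnc"].idxmax()]
        else:
            row = conv.loc[conv["objective"].idxmin()]
        return row[cols].to_numpy(dtype=float)

    def scale(self, alpha=None) -> np.ndarray:
        alpha = self.params if alpha is None else np.asarray(alpha, dtype=float)
        return apply_scaling(self.model.data,
                             ScalingScheme.alpha_over_sigma(alpha))

    def cluster(self, alpha=None, seed: int | None = 0,
                restarts: int = 20) -> np.ndarray:
        if self.model.n_clusters is None:
            raise ValueError("model has no cluster count")
        return cluster_kmeans(self.scale(alpha), self.model.n_clusters,
                              seed=seed, restarts=restarts)

    def evaluate(self, alpha=None, seed: int | None = 0) -> tuple[float, float]:
        """(ARI_fnc, AMI_max) of k-means on the data scaled by alpha/sigma."""
        if self.model.reference is None:
            raise ValueError("model has no reference partition")
        return evaluate_run(self.cluster(alpha, seed=seed),
                            self.model.reference)

    def summary(self) -> str:
        """Plain-text report of the fit."""
        m = self.model
        lines = [
            "Shape-complexity scaling results",
            "=" * 40,
            f"samples (n_orig):      {m.data.n_orig}",
            f"unique samples (n):    {m.data.n}",
            f"dimensions (d):        {m.data.d}",
            f"mode:                  {self.run.mode}",
            f"trials:                {len(self.trials)}",
            f"converged:             {self.n_converged}"
            f"  (discard fraction {self.discard_fraction:.2%})",
        ]
        alpha = self.params
        lines.append("selected alpha:        "
                     + "  ".join(f"{a:.4g}" for a in alpha))
        lines.append("alpha/sigma factors:   "
                     + "  ".join(f"{a:.4g}" for a in alpha / m.data.sigma))
        if "ari_fnc" in self.trials.columns and self.n_converged:
            lo, hi = self.run.interval("ari_fnc")
            lo2, hi2 = self.run.interval("ami_max")
            lines += [
                f"ARI_fnc over trials:   [{lo:.3f}, {hi:.3f}]",
                f"AMI_max over trials:   [{lo2:.3f}, {hi2:.3f}]",
            ]
        return "\n".join(lines)

    def plot_index_scatter(self, ax=None):
        """ARI_fnc vs AMI_max across trials (one point per converged trial)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ev = self.run.evaluated
        ax.scatter(ev["ami_max"], ev["ari_fnc"], s=8)
        ax.set_xlabel("AMI_max")
        ax.set_ylabel("ARI_fnc")
        return ax
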