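"""Multi-start optimization of scaling factors.

Two formulations are supported.

Problem P (the default) minimizes the squared orthogonality residual

    ( sum_{i<j} r_ij^-3 N^-1 (rho_ij1^2 - rho_ij2^2) )^2

subject to sum_k alpha_k^2 = d and alpha_k >= 1e-5.  Its solutions
approximate the first-order stationarity condition of SC on the sphere,
i.e. the equilibrium g'_k / g = -h'_k / h for every dimension.  The
dimension pair (1, 2) is the canonical choice; an ``all_pairs`` variant
sums the squared residual over every pair k < l.

The max-SC alternative maximizes SC itself subject only to the box
alpha_k >= 1e-5.  Because SC is radially invariant and can be unbounded
along rays that de-weight dimensions on which distinct samples coincide,
max-SC trials may run away to very large factors and terminate without
formal convergence; such trials are flagged, not discarded here.

Each trial draws its initial point from [0.5, 1.5]^d (Problem P) or
[1e-5, 1]^d (max-SC) using an independent, counter-derived substream of
the master seed, so trial results are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import (
    ALPHA_MIN,
    DataMatrix,
    _as_alpha,
    standardized_sq_diffs,
)

Mode = Literal["problem_p", "max_sc"]


@dataclass(frozen=True)
class TrialConfig:
    """Solver settings shared by all trials.

    max_iterations mirrors the usual local-NLP cap of 5000; ftol is the
    SLSQP objective-change criterion (the Problem-P objective is a square
    with typical feasible-point magnitude ~1e-9, so this must sit far
    below it); constraint_tol is the post-hoc feasibility requirement for
    declaring a trial converged.
    """

    max_iterations: int = 5000
    ftol: float = 1e-16
    constraint_tol: float = 1e-6
    gradient: Literal["fd", "analytic"] = "fd"
    objective_variant: Literal["pair12", "all_pairs"] = "pair12"


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one local solve."""

    trial_id: int
    init_alpha: np.ndarray
    alpha: np.ndarray
    objective: float
    converged: bool
    iterations: int
    mode: Mode = "problem_p"


def objective_p(rho2: np.ndarray, factors, N: int,
                variant: str = "pair12") -> float:
    """Problem-P objective (squared orthogonality residual).

    ``pair12`` uses dimensions (1, 2); ``all_pairs`` sums the squared
    residual over all dimension pairs k < l.
    """
    alpha = _as_alpha(factors)
    d = rho2.shape[1]
    if d < 2:
        raise ValueError("Problem P requires at least 2 dimensions")
    w = (rho2 @ (alpha * alpha)) ** -1.5
    t = rho2.T @ w / N  # t_k = N^-1 sum_{i<j} r_ij^-3 rho_ijk^2
    if variant == "pair12":
        return float((t[0] - t[1]) ** 2)
    if variant == "all_pairs":
        diffs = t[:, None] - t[None, :]
        return float(np.sum(np.triu(diffs, k=1) ** 2))
    raise ValueError(f"unknown objective variant: {variant!r}")


def objective_p_gradient(rho2: np.ndarray, factors, N: int,
                         variant: str = "pair12") -> np.ndarray:
    """Analytic gradient of :func:`objective_p`."""
    alpha = _as_alpha(factors)
    r2 = rho2 @ (alpha * alpha)
    w3 = r2 ** -1.5
    w5 = r2 ** -2.5
    t = rho2.T @ w3 / N
    # dt_l/dalpha_k = -3 alpha_k N^-1 sum r^-5 rho_ijl^2 rho_ijk^2
    if variant == "pair12":
        s = t[0] - t[1]
        diff12 = rho2[:, 0] - rho2[:, 1]
        ds = -3.0 * alpha * (rho2.T @ (w5 * diff12)) / N
        return 2.0 * s * ds
    grad = np.zeros_like(alpha)
    d = rho2.shape[1]
    for k in range(d):
        for l in range(k + 1, d):
            s = t[k] - t[l]
            diff = rho2[:, k] - rho2[:, l]
            ds = -3.0 * alpha * (rho2.T @ (w5 * diff)) / N
            grad += 2.0 * s * ds
    return grad


def neg_sc(rho2: np.ndarray, alpha: np.ndarray) -> float:
    """-SC(alpha), evaluated at the sphere-normalized point for stability.

    Radial invariance makes the rescaling exact, and it keeps g and h in a
    benign floating-point range even when the iterates grow huge.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = alpha * np.sqrt(alpha.size / float(alpha @ alpha))
    r2 = rho2 @ (beta * beta)
    g = np.sqrt(r2.sum())
    h = np.sum(r2 ** -0.5)
    return float(-g * h)


def neg_sc_gradient(rho2: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gradient of -SC at alpha (computed at the normalized point, rescaled back).

    SC(t*alpha) = SC(alpha) implies grad SC(alpha) = t * grad SC(t*alpha).
    """
    alpha = np.asarray(alpha, dtype=float)
    t = np.sqrt(alpha.size / float(alpha @ alpha))
    beta = alpha * t
    r2 = rho2 @ (beta * beta)
    g = np.sqrt(r2.sum())
    h = np.sum(r2 ** -0.5)
    gk = beta / g * rho2.sum(axis=0)
    hk = -beta * (rho2.T @ r2 ** -1.5)
    return -t * (gk * h + g * hk)


def _rho2_of(data) -> tuple[np.ndarray, int]:
    if isinstance(data, DataMatrix):
        return standardized_sq_diffs(data), data.N
    raise TypeError("expected a DataMatrix")


def solve_problem_p(data, init_alpha, config: TrialConfig | None = None,
                    *, trial_id: int = 0,
                    _rho2: np.ndarray | None = None,
                    _N: int | None = None) -> TrialResult:
    """One local solve of Problem P from ``init_alpha`` (SLSQP).

    The gradient is finite-difference by default; pass a config with
    ``gradient="analytic"`` for the exact gradient (identical minima,
    much faster).  A trial is converged when the solver reports success
    and the sphere residual is within ``config.constraint_tol``.
    """
    cfg = config or TrialConfig()
    if _rho2 is None:
        _rho2, _N = _rho2_of(data)
    rho2, N = _rho2, _N
    d = rho2.shape[1]
    x0 = np.asarray(init_alpha, dtype=float)
    if x0.size != d:
        raise ValueError("init_alpha dimension mismatch")

    jac = None
    if cfg.gradient == "analytic":
        jac = lambda a: objective_p_gradient(rho2, a, N, cfg.objective_variant)
    res = minimize(
        lambda a: objective_p(rho2, a, N, cfg.objective_variant),
        x0,
        jac=jac,
        method="SLSQP",
        bounds=[(ALPHA_MIN, None)] * d,
        constraints=[{"type": "eq", "fun": lambda a: a @ a - d,
                      "jac": lambda a: 2.0 * a}],
        options={"maxiter": cfg.max_iterations, "ftol": cfg.ftol},
    )
    resid = abs(float(res.x @ res.x) - d)
    feasible = resid <= cfg.constraint_tol and np.all(res.x >= ALPHA_MIN - 1e-12)
    return TrialResult(
        trial_id=trial_id, init_alpha=x0, alpha=res.x,
        objective=float(res.fun), converged=bool(res.success and feasible),
        iterations=int(res.nit), mode="problem_p",
    )


def solve_max_sc(data, init_alpha, config: TrialConfig | None = None,
                 *, trial_id: int = 0,
                 _rho2: np.ndarray | None = None) -> TrialResult:
    """One local max-SC solve (L-BFGS-B on -SC with the box alpha_k >= 1e-5).

    ``objective`` on the result is the attained SC value.  SC can be
    unbounded along some rays, in which case the solver stops at the
    iteration cap and the trial is flagged converged=False.
    """
    cfg = config or TrialConfig()
    if _rho2 is None:
        _rho2, _ = _rho2_of(data)
    rho2 = _rho2
    d = rho2.shape[1]
    x0 = np.asarray(init_alpha, dtype=float)

    jac = None
    if cfg.gradient == "analytic":
        jac = lambda a: neg_sc_gradient(rho2, a)
    res = minimize(
        lambda a: neg_sc(rho2, a),
        x0,
        jac=jac,
        method="L-BFGS-B",
        bounds=[(ALPHA_MIN, None)] * d,
        options={"maxiter": cfg.max_iterations},
    )
    return TrialResult(
        trial_id=trial_id, init_alpha=x0, alpha=res.x,
        objective=float(-res.fun), converged=bool(res.success),
        iterations=int(res.nit), mode="max_sc",
    )


def run_trials(data: DataMatrix, n_trials: int, seed: int | None = None,
               mode: Mode = "problem_p",
               config: TrialConfig | None = None) -> list[TrialResult]:
    """Run the multi-start trial protocol.

    Initial points are uniform on [0.5, 1.5]^d for Problem P and on
    [1e-5, 1]^d for max-SC.  Each trial uses an independent substream of
    the master seed (SeedSequence spawn), so the list is reproducible and
    individual trials could be re-run in any order.  Non-converged trials
    are retained but flagged; see :func:`discard_fraction`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfg = config or TrialConfig()
    rho2, N = _rho2_of(data)
    d = data.d
    lo, hi = (0.5, 1.5) if mode == "problem_p" else (ALPHA_MIN, 1.0)
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    results = []
    for t, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        x0 = rng.uniform(lo, hi, d)
        if mode == "problem_p":
            res = solve_problem_p(data, x0, cfg, trial_id=t, _rho2=rho2, _N=N)
        elif mode == "max_sc":
            res = solve_max_sc(data, x0, cfg, trial_id=t, _rho2=rho2)
        else:
            raise ValueError(f"unknown mode: {mode!r}")
        results.append(res)
    return results


def discard_fraction(trials: Sequence[TrialResult]) -> float:
    """Fraction of trials flagged non-converged (the discard rate)."""
    if not trials:
        return 0.0
    return sum(not t.converged for t in trials) / len(trials)
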