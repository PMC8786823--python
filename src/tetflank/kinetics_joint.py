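"""Coupled competitive kinetic fit of per-context oxidation time series.

In a competitive reaction every context is oxidized by the same enzyme
pool, so at each sampling point the relative turnover of all contexts is
known even though absolute reaction times are not.  Product fractions are
modeled as first-order monoexponential progress curves

    z_i(t_j) = 1 - exp(-k_i * t_j)

and the 256 context rate constants k_i are estimated jointly with the
latent measurement times t_j by least squares; the time scale is pinned by
t_1 = 1, so rates are in reciprocal units of the first sampling time.

The optimizer is a bounded trust-region least-squares solver with the
analytic Jacobian (dz/dk = t e^{-kt}, dz/dt = k e^{-kt}); initialization
is k_i = 1, t_j = 0.5 (j >= 2) with a budget of 100,000 residual
evaluations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

K_MAX = 1e3  # rate bound, in 1/t_1 units
T_MAX = 1e2  # latent-time bound, in t_1 units


def monoexp(t, k):
    """First-order product fraction 1 - exp(-k t)."""
    t = np.asarray(t, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(t < 0) or np.any(k < 0):
        raise ValueError("t and k must be non-negative")
    return -np.expm1(-k * t)


@dataclass
class TimeSeriesMatrix:
    """Observed product fractions, time points x contexts."""

    y: pd.DataFrame  # rows: time-point labels, columns: contexts

    def __post_init__(self) -> None:
        vals = self.y.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("product fractions must lie in [0, 1]")
        if self.y.shape[0] < 1:
            raise ValueError("need at least one time point")
        self.y = self.y.reindex(columns=sorted(self.y.columns))

    @classmethod
    def from_profiles(cls, profiles: list[pd.DataFrame]) -> "TimeSeriesMatrix":
        """Stack context-profile tables (one per time point) into a matrix.

        Low-coverage contexts are entered as NaN and dropped from the fit.
        """
        rows = {}
        for j, prof in enumerate(profiles, start=1):
            vals = prof["value"]
            if "low_coverage" in prof:
                vals = vals.mask(prof["low_coverage"].astype(bool))
            rows[f"t{j}"] = vals
        return cls(y=pd.DataFrame(rows).T)


@dataclass
class JointFitResult:
    k: pd.Series  # per-context rate constants (1/t_1 units)
    t: np.ndarray  # latent times, t[0] == 1 exactly
    objective: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.k.rename("k").rename_axis("context").to_csv(path, sep="\t")

    def meta_to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "t": list(map(float, self.t)),
                    "objective": self.objective,
                    "converged": self.converged,
                    "diagnostics": self.diagnostics,
                },
                indent=2,
            )
            + "\n"
        )


def _objective(k: np.ndarray, t: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    z = -np.expm1(-np.outer(t, k))
    return float(np.nansum(((y - z) ** 2)[mask]))


def joint_fit(
    Y: TimeSeriesMatrix,
    init_k: float = 1.0,
    init_t: float = 0.5,
    max_evals: int = 100_000,
    tol: float = 1e-12,
    n_starts: int = 1,
    seed: int | None = None,
    weights: np.ndarray | pd.DataFrame | None = None,
) -> JointFitResult:
    """Simultaneous estimate of context rates and latent measurement times.

    Minimizes sum_j sum_i (y_ij - (1 - e^{-k_i t_j}))^2 over k_i >= 0 and
    t_j >= 0 with t_1 = 1 fixed.  NaN entries (low-coverage contexts)
    contribute no residual.  With a single time point the problem has the
    closed form k_i = -ln(1 - y_i1), which is returned directly.
    ``n_starts > 1`` adds jittered restarts as a ruggedness check.

    ``weights`` (optional, same shape as Y, e.g. molecule counts per
    context and time point) turns the objective into weighted least
    squares; the default is the unweighted objective.
    """
    y = Y.y.to_numpy(dtype=float)
    n_times, n_ctx = y.shape
    contexts = list(Y.y.columns)
    mask = np.isfinite(y)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weights must match the shape of Y")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        sqrt_w = np.sqrt(w / np.nanmean(w[mask]))
    else:
        sqrt_w = np.ones_like(y)
    if not mask.any(axis=0).all():
        bad = [c for c, ok in zip(contexts, mask.any(axis=0)) if not ok]
        raise ValueError(f"columns with no data: {bad[:5]}{'...' if len(bad) > 5 else ''}")

    if not np.nansum(np.abs(y)) > 0:
        warnings.warn("all-zero observation matrix: rates unidentifiable, returning k=0", stacklevel=2)
        return JointFitResult(
            k=pd.Series(0.0, index=contexts),
            t=np.concatenate([[1.0], np.zeros(n_times - 1)]) if n_times else np.array([1.0]),
            objective=0.0,
            converged=True,
            diagnostics={"note": "all-zero Y"},
        )

    if n_times == 1:
        k = -np.log1p(-np.clip(y[0], 0.0, 1.0 - 1e-15))
        return JointFitResult(
            k=pd.Series(k, index=contexts),
            t=np.array([1.0]),
            objective=0.0,
            converged=True,
            diagnostics={"note": "single time point, closed form"},
        )

    yv = np.where(mask, y, 0.0)

    wmask = sqrt_w * mask

    def residuals(theta: np.ndarray) -> np.ndarray:
        k = theta[:n_ctx]
        t = np.concatenate([[1.0], theta[n_ctx:]])
        z = -np.expm1(-np.outer(t, k))
        return ((yv - z) * wmask).ravel()

    def jacobian(theta: np.ndarray) -> np.ndarray:
        k = theta[:n_ctx]
        t = np.concatenate([[1.0], theta[n_ctx:]])
        e = np.exp(-np.outer(t, k))  # (n_times, n_ctx)
        jac = np.zeros((n_times * n_ctx, n_ctx + n_times - 1))
        rows = np.arange(n_times * n_ctx).reshape(n_times, n_ctx)
        # d residual / d k_i = -t_j e^{-k_i t_j}
        for j in range(n_times):
            jac[rows[j], np.arange(n_ctx)] = -(t[j] * e[j]) * wmask[j]
        # d residual / d t_j = -k_i e^{-k_i t_j}, j >= 2
        for j in range(1, n_times):
            jac[rows[j], n_ctx + j - 1] = -(k * e[j]) * wmask[j]
        return jac

    lower = np.zeros(n_ctx + n_times - 1)
    upper = np.concatenate([np.full(n_ctx, K_MAX), np.full(n_times - 1, T_MAX)])

    theta0 = np.concatenate([np.full(n_ctx, init_k), np.full(n_times - 1, init_t)])
    starts = [theta0]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            jitter = rng.lognormal(mean=0.0, sigma=0.5, size=theta0.size)
            starts.append(np.clip(theta0 * jitter, lower, upper))

    best = None
    for start in starts:
        sol = least_squares(
            residuals,
            start,
            jac=jacobian,
            bounds=(lower, upper),
            method="trf",
            ftol=tol,
            xtol=tol,
            gtol=tol,
            max_nfev=max_evals,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    k = best.x[:n_ctx]
    t = np.concatenate([[1.0], best.x[n_ctx:]])
    objective = float(2.0 * best.cost)  # least_squares cost = 0.5 * SSQ
    init_obj = _objective(np.full(n_ctx, init_k), np.concatenate([[1.0], np.full(n_times - 1, init_t)]), yv, mask)
    converged = bool(best.status > 0)
    if not converged:
        warnings.warn("joint fit did not converge within the evaluation budget", stacklevel=2)
    return JointFitResult(
        k=pd.Series(k, index=contexts),
        t=t,
        objective=objective,
        converged=converged,
        diagnostics={
            "status": int(best.status),
            "nfev": int(best.nfev),
            "optimality": float(best.optimality),
            "initial_objective": init_obj,
            "active_lower_k": int(np.sum(k <= 1e-12)),
            "active_upper_k": int(np.sum(k >= K_MAX * (1 - 1e-9))),
            "n_starts": len(starts),
        },
    )


def fold_ratio(result: JointFitResult, exclude: list[str] | None = None) -> float:
    """Max/min ratio of fitted rate constants (flanking-effect strength).

    ``exclude`` drops flagged (e.g. low-coverage) contexts before taking
    the extremes.  Invariant under the joint (k, 1/t) rescaling gauge.
    """
    k = result.k.drop(index=exclude) if exclude else result.k
    k = k[k > 0]
    if k.empty:
        raise ValueError("no positive rate constants")
    return float(k.max() / k.min())
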