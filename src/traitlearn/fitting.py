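"""Least-squares model fitting and BIC scoring.

A model is fitted per participant by minimizing the sum of squared errors
(SSE) between the model's trial-by-trial predictions and the participant's
responses over all runs, with the Nelder-Mead simplex started from parameter
midpoints.  Missing responses are excluded from the SSE but the model still
updates on the shown feedback.  Model evidence is the Bayesian information
criterion::

    BIC = n * ln(SSE / n) + k * ln(n)

with ``n`` the number of scored trials and ``k`` the number of free
parameters (lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .design import ExperimentDesign
from .models import (
    ModelSpec,
    RunSet,
    midpoint_params,
    param_bounds,
    predict_series,
)

#: SSE floor before the log in the BIC (exact zero is only reachable on
#: synthetic noise-free data).
SSE_FLOOR = 1e-12

DEFAULT_XATOL = 1e-6
DEFAULT_FATOL = 1e-6
DEFAULT_MAXFEV = 2000
#: The simplex search restarts from its own solution (fresh simplex) until
#: the objective stops improving, up to this many times.  Nelder-Mead can
#: collapse prematurely on ridge-shaped SSE surfaces; restarting from the
#: collapsed point is the standard remedy and keeps the search deterministic.
DEFAULT_RESTARTS = 3


@dataclass
class FitResult:
    """Outcome of fitting one model to one participant."""

    spec: ModelSpec
    params: dict[str, float]
    sse: float
    n_trials_used: int
    bic: float
    converged: bool
    n_obj_evals: int


def compute_bic(sse: float, n: int, k: int) -> float:
    """BIC = n*ln(SSE/n) + k*ln(n); SSE is floored at 1e-12."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if sse < 0:
        raise ValueError("SSE cannot be negative")
    sse = max(float(sse), SSE_FLOOR)
    return n * np.log(sse / n) + k * np.log(n)


def _project(x: np.ndarray, bounds: Sequence[tuple[float, float]]) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def sse_objective(
    params: Mapping[str, float] | np.ndarray,
    spec: ModelSpec,
    runs: RunSet,
    design: ExperimentDesign,
    rp=None,
    sim=None,
) -> float:
    """Summed squared prediction error over all runs and non-missing trials.

    Array-valued parameters (in ``spec.param_names`` order) are projected onto
    their bounds before evaluation, so an unconstrained simplex search can use
    this objective directly.
    """
    if runs.responses is None:
        raise ValueError("runs carry no responses to fit")
    if isinstance(params, np.ndarray) or isinstance(params, (list, tuple)):
        bounds = list(param_bounds(spec, design).values())
        x = _project(np.asarray(params, dtype=float), bounds)
        params = dict(zip(spec.param_names, x))
    if not np.isfinite(runs.responses).any():
        raise ValueError("all trials missing")
    preds = predict_series(spec, params, runs, design, rp=rp, sim=sim)
    err = runs.responses - preds
    return float(np.nansum(err * err))


def _n_used(runs: RunSet) -> int:
    return int(np.isfinite(runs.responses).sum())


def _fit_m1_ols(
    spec: ModelSpec, runs: RunSet, design: ExperimentDesign, rp
) -> tuple[dict[str, float], float]:
    """Exact OLS of responses on reference-point values (the M1 minimizer)."""
    rp_v = np.asarray(rp.rp if hasattr(rp, "rp") else rp, dtype=float)
    x = rp_v[runs.orders].ravel()
    y = runs.responses.ravel()
    keep = np.isfinite(y)
    X = np.column_stack([np.ones(keep.sum()), x[keep]])
    coef, _, _, _ = np.linalg.lstsq(X, y[keep], rcond=None)
    b0, b1 = float(coef[0]), float(coef[1])
    resid = y[keep] - (b0 + b1 * x[keep])
    return {"b0": b0, "b1": b1}, float(resid @ resid)


def fit_model(
    spec: ModelSpec,
    runs: RunSet,
    design: ExperimentDesign,
    rp=None,
    sim=None,
    xatol: float = DEFAULT_XATOL,
    fatol: float = DEFAULT_FATOL,
    maxfev: int = DEFAULT_MAXFEV,
    n_starts: int = 1,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int | np.random.SeedSequence | None = None,
) -> FitResult:
    """Fit one model to one participant's runs.

    M1 is solved exactly by ordinary least squares; the other models use an
    unconstrained Nelder-Mead search from the parameter midpoints with bound
    projection inside the objective.  The simplex is restarted from its own
    solution until converged (``n_restarts``); ``n_starts > 1`` adds extra
    random starting points (off by default) and keeps the best.
    """
    n = _n_used(runs)
    if n == 0:
        raise ValueError("all trials missing")

    if spec.model_id == "M1":
        params, sse = _fit_m1_ols(spec, runs, design, rp)
        return FitResult(spec, params, sse, n, compute_bic(sse, n, spec.k_free), True, 1)

    bounds = list(param_bounds(spec, design).values())
    evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        p = dict(zip(spec.param_names, _project(x, bounds)))
        return sse_objective(p, spec, runs, design, rp=rp, sim=sim)

    x0s = [np.array(list(midpoint_params(spec, design).values()))]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            x0s.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best = None
    converged = False
    for x0 in x0s:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev},
        )
        for _ in range(n_restarts):
            # restart from the projected point: when the simplex has wandered
            # onto the flat projected region outside the bounds, a fresh
            # simplex on the boundary sees the feasible-side descent again
            again = optimize.minimize(
                objective,
                _project(res.x, bounds),
                method="Nelder-Mead",
                options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev},
            )
            if again.fun < res.fun - 1e-9:
                res = again
            else:
                res = again if again.fun < res.fun else res
                break
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    x = _project(best.x, bounds)
    params = dict(zip(spec.param_names, (float(v) for v in x)))
    sse = float(best.fun)
    return FitResult(spec, params, sse, n, compute_bic(sse, n, spec.k_free), converged, evals)


def fit_models(
    specs: Sequence[ModelSpec],
    runs: RunSet,
    design: ExperimentDesign,
    rp=None,
    sim=None,
    stereotype_rp=None,
    self_rp=None,
    **options,
) -> list[FitResult]:
    """Fit a whole model set, routing each spec to its reference point."""
    by_source = {"population": rp, "none": rp, "stereotype": stereotype_rp, "self": self_rp}
    out = []
    for spec in specs:
        rp_used = by_source[spec.rp_source]
        if spec.uses_rp and rp_used is None:
            raise ValueError(f"no reference point supplied for {spec.label}")
        out.append(fit_model(spec, runs, design, rp=rp_used, sim=sim, **options))
    return out
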