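"""Change-point (segmented) regression for the OR-workload effect.

The mean log duration is allowed to depend on the OR daily workload x
through a continuous one-knot piecewise-linear ("hinge") term::

    f(x) = slope_lo * min(x, c) + slope_hi * max(x - c, 0)

with both segments and the breakpoint c estimated jointly with the full
set of duration covariates.  Two estimators are provided:

* :func:`fit_segmented_iterative` — iterative linearization: at a working
  breakpoint c the hinge is expanded to first order in c, the resulting
  linear model is refit, and the breakpoint is updated from the ratio of
  the first-order coefficient to the segment-difference coefficient.
  This is the fast estimator used by the pipeline.
* :func:`fit_segmented_grid` — exhaustive profiling of the residual sum
  of squares over a breakpoint grid; slower, but global.  It serves as
  the correctness oracle for the iterative estimator: on data where the
  iterative fit converges, the two agree to within one grid step.

The breakpoint is continuous even though the workload is an integer
count; the search interval excludes the outer 5% of the covariate range
so both segments keep enough support to be estimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import HINGE_HI, HINGE_LO, ModelSpec, ModelFit, _ols_fit, build_design

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 50
#: fraction of the covariate range excluded at each end of the search
EDGE_FRACTION = 0.05


def hinge_basis(x, c: float):
    """The continuous one-knot hinge basis ``(min(x, c), max(x - c, 0))``.

    Accepts a scalar or array workload ``x >= 1`` and breakpoint ``c > 0``;
    the two components always sum to x, which keeps the fitted mean
    continuous in x at the knot.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa <= 0):
        raise ValueError("workload x must be positive")
    if c <= 0:
        raise ValueError(f"breakpoint must be positive, got {c}")
    b_lo = np.minimum(xa, c)
    b_hi = np.maximum(xa - c, 0.0)
    if np.isscalar(x) or xa.ndim == 0:
        return float(b_lo), float(b_hi)
    return b_lo, b_hi


@dataclass
class SegmentedFit:
    """A fitted one-knot segmented model for the workload covariate."""

    c_hat: float
    slope_lo: float
    slope_hi: float
    se_lo: float
    se_hi: float
    ci_lo: tuple[float, float]
    ci_hi: tuple[float, float]
    n_iter: int
    converged: bool
    trace: list[float]
    rss: float
    slope_diff_p: float  #: p-value for "no kink" (equal segment slopes)
    no_changepoint_flag: bool  #: True when the slope difference is not significant
    model: ModelFit | None = None  #: full-model refit at the final breakpoint

    def to_dict(self) -> dict:
        return {
            "c_hat": self.c_hat,
            "slope_lo": self.slope_lo,
            "slope_hi": self.slope_hi,
            "se_lo": self.se_lo,
            "se_hi": self.se_hi,
            "ci_lo": list(self.ci_lo),
            "ci_hi": list(self.ci_hi),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "rss": self.rss,
            "slope_diff_p": self.slope_diff_p,
            "no_changepoint_flag": self.no_changepoint_flag,
            "trace": self.trace,
        }


def _search_interval(x: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    delta = EDGE_FRACTION * (hi - lo)
    return lo + delta, hi - delta


def _design_parts(
    rows: pd.DataFrame, covariate: str, full_model: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Z, x, y): non-workload design, workload, outcome."""
    X, y, _ = build_design(rows, full_model, include_or_workload=False)
    x = rows[covariate].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError(
            f"covariate {covariate!r} takes fewer than 3 distinct values; "
            "a breakpoint is not identifiable"
        )
    Z = np.column_stack([np.ones(len(rows)), X.to_numpy(dtype=float)])
    return Z, x, y.to_numpy(dtype=float)


def _rss_at(Z: np.ndarray, x: np.ndarray, y: np.ndarray, c: float) -> float:
    b_lo, b_hi = hinge_basis(x, c)
    A = np.column_stack([Z, b_lo, b_hi])
    _, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if res.size:
        return float(res[0])
    r = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(r @ r)


def _final_fit(
    rows: pd.DataFrame,
    covariate: str,
    full_model: ModelSpec,
    c: float,
    n_iter: int,
    converged: bool,
    trace: list[float],
) -> SegmentedFit:
    """Refit the full model in the two-slope basis at the final breakpoint
    and assemble the report."""
    from dataclasses import replace as _replace

    spec_c = _replace(full_model, breakpoint=float(c), include_or_hinge=True)
    X, y, refs = build_design(rows, spec_c)
    fit = _ols_fit(X, y, spec_c, refs)
    t = fit.table
    slope_lo = float(t.loc[HINGE_LO, "estimate"])
    slope_hi = float(t.loc[HINGE_HI, "estimate"])
    se_lo = float(t.loc[HINGE_LO, "se"])
    se_hi = float(t.loc[HINGE_HI, "se"])
    # test of equal segment slopes (no change point) via the difference
    import scipy.stats

    Z, x, yv = _design_parts(rows, covariate, full_model)
    b_lo, b_hi = hinge_basis(x, c)
    A = np.column_stack([Z, b_lo, b_hi])
    coef, _, _, _ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ coef
    dof = len(yv) - A.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(A.T @ A)
    j_lo, j_hi = A.shape[1] - 2, A.shape[1] - 1
    var_diff = cov[j_hi, j_hi] + cov[j_lo, j_lo] - 2 * cov[j_hi, j_lo]
    tstat = (coef[j_hi] - coef[j_lo]) / np.sqrt(max(var_diff, 1e-300))
    p_diff = float(2 * scipy.stats.t.sf(abs(tstat), dof))
    return SegmentedFit(
        c_hat=float(c),
        slope_lo=slope_lo,
        slope_hi=slope_hi,
        se_lo=se_lo,
        se_hi=se_hi,
        ci_lo=(float(t.loc[HINGE_LO, "ci_low"]), float(t.loc[HINGE_LO, "ci_high"])),
        ci_hi=(float(t.loc[HINGE_HI, "ci_low"]), float(t.loc[HINGE_HI, "ci_high"])),
        n_iter=n_iter,
        converged=converged,
        trace=trace,
        rss=float(resid @ resid),
        slope_diff_p=p_diff,
        no_changepoint_flag=p_diff >= 0.05,
        model=fit,
    )


def fit_segmented_iterative(
    rows: pd.DataFrame,
    covariate: str = "or_daily_n",
    full_model: ModelSpec | None = None,
    c0: float | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SegmentedFit:
    """Estimate the breakpoint by iterative linearization with descent
    safeguards.

    At working breakpoint c the model ``.. + beta*x + delta*(x-c)+`` is
    augmented with the first-order term ``gamma * (-1[x > c])``; after an
    OLS refit the breakpoint moves by ``gamma / delta``, with the step
    halved until the residual sum of squares improves (the raw update can
    oscillate on weak kinks).  Because the RSS profile in c is only
    piecewise smooth on an integer workload and can hold near-tied local
    minima on either side of a knot, the iteration is restarted from every
    local minimum of a coarse profile scan and the lowest-RSS fit is
    returned.  Iteration stops when the move is below ``tol``;
    non-convergence within ``max_iter`` returns ``converged=False`` with
    the trace rather than raising.  The two reported slopes are ``beta``
    and ``beta + delta`` from a final refit in the two-slope hinge basis.
    """
    if full_model is None:
        full_model = ModelSpec(workload_form="count")
    Z, x, y = _design_parts(rows, covariate, full_model)
    lo, hi = _search_interval(x)
    if c0 is None:
        coarse = np.arange(lo, hi + 1e-9, 0.25)
        prof = np.array([_rss_at(Z, x, y, cc) for cc in coarse])
        starts = [
            float(coarse[i])
            for i in range(len(coarse))
            if (i == 0 or prof[i] <= prof[i - 1])
            and (i == len(coarse) - 1 or prof[i] <= prof[i + 1])
        ]
    else:
        starts = [min(max(float(c0), lo), hi)]
    best = None
    for start in starts:
        run = _muggeo_descent(Z, x, y, start, lo, hi, tol, max_iter)
        if best is None or run[3] < best[3] - 1e-12:
            best = run
    c, it, converged, _rss, trace = best[0], best[1], best[2], best[3], best[4]
    return _final_fit(rows, covariate, full_model, c, it, converged, trace)


def _muggeo_descent(
    Z: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    c0: float,
    lo: float,
    hi: float,
    tol: float,
    max_iter: int,
) -> tuple[float, int, bool, float, list[float]]:
    """One damped linearization run; returns (c, n_iter, converged, rss,
    trace)."""
    c = c0
    rss_c = _rss_at(Z, x, y, c)
    trace = [c]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = np.maximum(x - c, 0.0)
        V = -(x > c).astype(float)
        A = np.column_stack([Z, x, U, V])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        delta, gamma = coef[-2], coef[-1]
        if delta == 0.0:  # flat slope difference: no identifiable kink here
            converged = True
            break
        c_new = min(max(c + gamma / delta, lo), hi)
        # step halving: accept only RSS-improving moves
        while abs(c_new - c) >= tol:
            if _rss_at(Z, x, y, c_new) < rss_c - 1e-12:
                break
            c_new = c + (c_new - c) / 2.0
        if abs(c_new - c) < tol:
            converged = True
            break
        c = c_new
        rss_c = _rss_at(Z, x, y, c)
        trace.append(c)
    return c, it, converged, rss_c, trace


def fit_segmented_grid(
    rows: pd.DataFrame,
    covariate: str = "or_daily_n",
    full_model: ModelSpec | None = None,
    grid: Sequence[float] | None = None,
    step: float = 0.05,
) -> SegmentedFit:
    """Profile the residual sum of squares over a breakpoint grid and
    return the minimiser.  With no explicit grid, a regular grid with the
    given step over the interior 90% of the covariate range is used."""
    if full_model is None:
        full_model = ModelSpec(workload_form="count")
    Z, x, y = _design_parts(rows, covariate, full_model)
    if grid is None:
        lo, hi = _search_interval(x)
        grid = np.arange(lo, hi + step / 2, step)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("breakpoint grid is empty")
    rss = np.array([_rss_at(Z, x, y, c) for c in grid])
    c_best = float(grid[int(np.argmin(rss))])
    return _final_fit(rows, covariate, full_model, c_best, len(grid), True, list(grid))
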