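"""Log-linear regression models of operative duration.

The outcome is the natural log of the cut-to-suture time in minutes,
regressed by ordinary least squares on:

* day of the week (categorical, reference Saturday),
* surgeon (categorical, reference = the most frequent surgeon),
* surgery type (categorical, reference = the most frequent type),
* anaesthetist (categorical, reference = the most frequent; can be dropped),
* OR daily workload through a continuous one-knot hinge
  ``(min(x, c), max(x - c, 0))`` at a breakpoint ``c``, and
* EITHER the surgeon's daily caseload as a continuous count ("model I")
  OR the position label ``k~j`` as a categorical ("model II").

Caseload and position are exactly collinear (k is the first field of the
label), so a spec never contains both.  A surgeon-by-position interaction
model extends model II.  Because the outcome is a log, a coefficient b is
a multiplicative effect exp(b) on the mean duration; the back-transform
helpers turn (intercept, coefficient) pairs into minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

#: significance-code scheme used in the coefficient tables
SIG_CODES = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "&"))

#: default decision threshold for hypothesis verdicts (stricter than the
#: display codes; raw p-values are always reported alongside)
DEFAULT_P_THRESHOLD = 0.005

HINGE_LO = "or_load_le_c"
HINGE_HI = "or_load_gt_c"
CASELOAD = "surgeon_daily_n"


def significance_code(p: float) -> str:
    """Map a two-sided p-value to the display code: ``***`` below 0.001,
    ``**`` below 0.01, ``*`` below 0.05, ``&`` below 0.1, ``$`` otherwise."""
    for cut, code in SIG_CODES:
        if p < cut:
            return code
    return "$"


@dataclass(frozen=True)
class ModelSpec:
    """Covariate specification for one duration model.

    ``workload_form`` selects the surgeon-workload encoding: ``"count"``
    (continuous daily caseload; model I) or ``"position"`` (categorical
    ``k~j`` label; model II).  ``breakpoint`` is the hinge knot for the OR
    workload, typically the estimate from the change-point stage.
    """

    workload_form: str = "count"  # "count" | "position" | "none"
    breakpoint: float = 4.0
    include_weekday: bool = True
    include_surgeon: bool = True
    include_type: bool = True
    include_anaesthetist: bool = True
    include_or_hinge: bool = True
    weekday_ref: str = "Sat"
    position_ref: str = "1~1"
    surgeon_ref: str | None = None  # None -> most frequent
    type_ref: str | None = None
    anaesthetist_ref: str | None = None

    def __post_init__(self) -> None:
        if self.workload_form not in ("count", "position", "none"):
            raise ValueError(f"unknown workload_form {self.workload_form!r}")


def model_i_spec(breakpoint: float = 4.0, **kw) -> ModelSpec:
    """Main-effects model with the continuous surgeon daily caseload."""
    return ModelSpec(workload_form="count", breakpoint=breakpoint, **kw)


def model_ii_spec(breakpoint: float = 4.0, **kw) -> ModelSpec:
    """Main-effects model with the categorical position label."""
    return ModelSpec(workload_form="position", breakpoint=breakpoint, **kw)


@dataclass
class ModelFit:
    """A fitted OLS duration model.

    ``table`` has one row per term (index = term name) with columns
    ``estimate``, ``se``, ``ci_low``, ``ci_high``, ``p``, ``code``.
    """

    table: pd.DataFrame
    r2: float
    adj_r2: float
    n: int
    df_resid: int
    references: dict[str, str]
    spec: ModelSpec | None = None
    dropped_terms: list[str] = field(default_factory=list)
    fitted: np.ndarray | None = None
    resid: np.ndarray | None = None

    @property
    def intercept(self) -> float:
        return float(self.table.loc["const", "estimate"])

    def params(self) -> pd.Series:
        return self.table["estimate"]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "references": self.references,
            "dropped_terms": self.dropped_terms,
            "coefficients": {
                term: {
                    k: (None if pd.isna(v) else v)
                    for k, v in row.items()
                }
                for term, row in self.table.to_dict(orient="index").items()
            },
        }


def _dummy_columns(s: pd.Series, var: str, ref: str | None) -> tuple[pd.DataFrame, str]:
    """Reference-coded dummy columns named ``var[level]``."""
    s = s.astype(str)
    counts = s.value_counts()
    if ref is None:
        ref = counts.index[0]  # most frequent level
    elif ref not in counts.index:
        raise ValueError(f"reference level {ref!r} absent from {var!r}")
    levels = [l for l in sorted(counts.index) if l != ref]
    cols = {f"{var}[{l}]": (s == l).astype(float) for l in levels}
    return pd.DataFrame(cols, index=s.index), str(ref)


def hinge_columns(x: "pd.Series | np.ndarray", c: float) -> pd.DataFrame:
    """The continuous one-knot hinge basis of the OR workload."""
    from .segmented import hinge_basis  # local to avoid import cycle at load

    b_lo, b_hi = hinge_basis(np.asarray(x, dtype=float), c)
    idx = x.index if isinstance(x, pd.Series) else None
    return pd.DataFrame({HINGE_LO: b_lo, HINGE_HI: b_hi}, index=idx)


def build_design(
    rows: pd.DataFrame, spec: ModelSpec, *, include_or_workload: bool | None = None
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Build (X, y, references) for a spec.  X excludes the constant.

    ``include_or_workload=False`` leaves the OR-workload columns out, which
    the change-point stage uses to supply its own working basis.
    """
    refs: dict[str, str] = {}
    parts: list[pd.DataFrame] = []
    if include_or_workload is None:
        include_or_workload = spec.include_or_hinge
    if spec.include_weekday:
        d, refs["weekday"] = _dummy_columns(rows["weekday"], "weekday", spec.weekday_ref)
        parts.append(d)
    if include_or_workload:
        parts.append(hinge_columns(rows["or_daily_n"], spec.breakpoint))
    if spec.workload_form == "count":
        parts.append(rows[[CASELOAD]].astype(float))
    elif spec.workload_form == "position":
        d, refs["position"] = _dummy_columns(
            rows["position_label"], "position", spec.position_ref
        )
        parts.append(d)
    if spec.include_surgeon:
        d, refs["surgeon"] = _dummy_columns(rows["surgeon"], "surgeon", spec.surgeon_ref)
        parts.append(d)
    if spec.include_type:
        d, refs["surgery_type"] = _dummy_columns(
            rows["surgery_type"], "surgery_type", spec.type_ref
        )
        parts.append(d)
    if spec.include_anaesthetist:
        d, refs["anaesthetist"] = _dummy_columns(
            rows["anaesthetist"], "anaesthetist", spec.anaesthetist_ref
        )
        parts.append(d)
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=rows.index)
    y = rows["log_duration"].astype(float)
    return X, y, refs


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise naming the aliased columns if the design (with constant) is
    rank deficient."""
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(A)
    if rank == A.shape[1]:
        return
    # identify aliased columns greedily by pivoted growth of the rank
    aliased = []
    keep = [0]
    for j in range(1, A.shape[1]):
        cand = A[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            aliased.append(X.columns[j - 1])
    raise ValueError(
        f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
        f"aliased terms: {aliased}"
    )


def _ols_fit(X: pd.DataFrame, y: pd.Series, spec: ModelSpec | None, refs: dict) -> ModelFit:
    n, k = len(X), X.shape[1] + 1
    if n <= k:
        raise ValueError(f"n = {n} observations for {k} parameters; model not estimable")
    _check_full_rank(X)
    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(y.to_numpy(dtype=float), exog).fit()
    names = ["const"] + list(X.columns)
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": res.pvalues,
        },
        index=names,
    )
    table["code"] = [significance_code(p) for p in table["p"]]
    return ModelFit(
        table=table,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n=n,
        df_resid=int(res.df_resid),
        references=refs,
        spec=spec,
        fitted=np.asarray(res.fittedvalues),
        resid=np.asarray(res.resid),
    )


def fit_model(rows: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit a main-effects duration model by OLS on log minutes.

    Raises if the design is rank deficient (naming the aliased terms) or
    if there are fewer observations than parameters.
    """
    X, y, refs = build_design(rows, spec)
    return _ols_fit(X, y, spec, refs)


def fit_interaction_model(
    rows: pd.DataFrame,
    base_spec: ModelSpec | None = None,
    interactions: tuple[str, str] = ("surgeon", "position"),
) -> ModelFit:
    """Fit model II plus surgeon-by-position interaction terms.

    Interaction columns are products of the two dummy sets; cells with no
    observations, and cells whose column is aliased with terms already in
    the design (which happens when a rare cell coincides with a single
    surgeon-day), are dropped with a logged notice (their names are
    recorded in ``dropped_terms``).  With a single surgeon the fit reduces
    to the position-only model.
    """
    if base_spec is None:
        base_spec = model_ii_spec()
    if base_spec.workload_form != "position":
        raise ValueError("interaction model extends the position-form (model II) spec")
    if interactions != ("surgeon", "position"):
        raise ValueError("only the surgeon x position interaction is supported")
    X, y, refs = build_design(rows, base_spec)
    a_cols = [c for c in X.columns if c.startswith("surgeon[")]
    b_cols = [c for c in X.columns if c.startswith("position[")]
    inter = {}
    dropped: list[str] = []
    # incremental orthogonalisation against the base design so aliased
    # interaction cells are dropped instead of sinking the whole fit
    base = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    Q, _ = np.linalg.qr(base)
    basis = [Q[:, i] for i in range(Q.shape[1])]
    for a in a_cols:
        for b in b_cols:
            name = f"{a}:{b}"
            col = (X[a] * X[b]).to_numpy(dtype=float)
            if col.sum() == 0:
                dropped.append(name)
                continue
            v = col.copy()
            for q in basis:
                v -= (q @ v) * q
            if np.linalg.norm(v) < 1e-8 * max(np.linalg.norm(col), 1.0):
                dropped.append(name)
                continue
            basis.append(v / np.linalg.norm(v))
            inter[name] = col
    if dropped:
        log.info(
            "interaction model: %d empty or aliased cells dropped: %s",
            len(dropped),
            dropped,
        )
    if inter:
        X = pd.concat([X, pd.DataFrame(inter, index=X.index)], axis=1)
    fit = _ols_fit(X, y, base_spec, refs)
    fit.dropped_terms = dropped
    return fit


@dataclass
class LassoSelection:
    """Result of L1-penalised variable selection."""

    selected: list[str]
    alpha: float
    coefficients: pd.Series  # on the standardized scale
    candidates: list[str]


def lasso_select(
    rows: pd.DataFrame,
    spec: ModelSpec,
    *,
    alphas: Sequence[float] | None = None,
    alpha: float | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> LassoSelection:
    """Select covariates by LASSO on the standardized design.

    Each dummy column is penalised separately (simple, not grouped,
    LASSO).  Covariates are standardized to unit variance and the outcome
    centered before fitting.  With ``alpha`` given, fits at that fixed
    penalty; otherwise the penalty is chosen by ``cv_folds``-fold
    cross-validation (shuffled with ``seed``, so the result is
    deterministic given the seed).  ``alpha=0`` is the OLS limit and
    selects every candidate.
    """
    X, y, _ = build_design(rows, spec)
    if y.std(ddof=0) < 1e-12:
        raise ValueError("outcome has zero variance; selection is undefined")
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = (Xv[:, keep] - Xv[:, keep].mean(axis=0)) / sd[keep]
    names = list(X.columns[keep])
    yc = y.to_numpy(dtype=float) - y.mean()
    if alpha is not None and alpha == 0.0:
        coef, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        sel = [n for n, b in zip(names, coef) if b != 0.0]
        return LassoSelection(sel, 0.0, pd.Series(coef, index=names), names)
    if alpha is not None:
        est = Lasso(alpha=alpha, fit_intercept=False, max_iter=50_000).fit(Xs, yc)
        coef = est.coef_
        best = alpha
    else:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        est = LassoCV(
            alphas=100 if alphas is None else alphas,
            cv=cv,
            fit_intercept=False,
            max_iter=50_000,
        ).fit(Xs, yc)
        coef = est.coef_
        best = float(est.alpha_)
    sel = [n for n, b in zip(names, coef) if abs(b) > 1e-12]
    return LassoSelection(sel, best, pd.Series(coef, index=names), names)


# ---------------------------------------------------------------------------
# back-transformation to minutes


def backtransform_mean_minutes(
    intercept: float, coef: float = 0.0, *, rounded: bool = True
) -> float:
    """Mean duration in minutes implied by (intercept + coefficient) on the
    log scale: ``exp(intercept + coef)``, rounded to whole minutes by
    default (set ``rounded=False`` for the unrounded value)."""
    v = float(np.exp(intercept + coef))
    return float(round(v)) if rounded else v


def backtransform_delta_minutes(
    intercept: float, coef: float, *, rounded: bool = True
) -> float:
    """How many minutes shorter (positive) or longer (negative) the mean
    duration is relative to the baseline:
    ``exp(intercept) - exp(intercept + coef)``."""
    v = float(np.exp(intercept) - np.exp(intercept + coef))
    return float(round(v)) if rounded else v
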