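"""Pipeline orchestration and report rendering.

Runs ingest -> features -> change point -> models (main effects in both
workload forms, the surgeon-by-position interaction model, and LASSO
selection), and renders the results as machine JSON plus human-readable
coefficient tables.  The rendered tables are a pure view of the machine
output: they contain exactly the same numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from . import features as _features
from . import ingest as _ingest
from .models import (
    DEFAULT_P_THRESHOLD,
    CASELOAD,
    HINGE_HI,
    HINGE_LO,
    LassoSelection,
    ModelFit,
    fit_interaction_model,
    fit_model,
    lasso_select,
    model_i_spec,
    model_ii_spec,
)
from .segmented import SegmentedFit, fit_segmented_iterative

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class WorkloadProfile:
    """Mean duration (minutes) by OR daily workload with t-based 95% CIs.

    ``table`` has one row per workload level: ``or_daily_n``, ``n``,
    ``mean_min``, ``ci_low``, ``ci_high``; levels observed once are
    reported without a CI (NaN bounds).
    """

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def workload_profile(rows: pd.DataFrame) -> WorkloadProfile:
    """Group mean cut-to-suture minutes by OR daily workload."""
    if rows.empty:
        raise ValueError("workload_profile: empty input")
    recs = []
    for x, g in rows.groupby("or_daily_n"):
        d = g["duration_min"].to_numpy(dtype=float)
        n = len(d)
        mean = float(d.mean())
        if n > 1:
            se = d.std(ddof=1) / np.sqrt(n)
            tq = scipy.stats.t.ppf(0.975, n - 1)
            lo, hi = mean - tq * se, mean + tq * se
        else:
            lo = hi = float("nan")
        recs.append(
            {"or_daily_n": int(x), "n": n, "mean_min": mean, "ci_low": lo, "ci_high": hi}
        )
    return WorkloadProfile(pd.DataFrame(recs))


def hypothesis_verdicts(
    model_count: ModelFit,
    model_position: ModelFit,
    segmented: SegmentedFit,
    threshold: float = DEFAULT_P_THRESHOLD,
) -> dict:
    """Structured verdicts on the four study hypotheses at the configured
    significance threshold (kept separate from the coefficient tables).

    H1: duration depends on surgery type and surgeon.
    H2: duration depends on the day of the week.
    H3a: duration decreases with the surgeon's daily caseload.
    H3b: duration decreases monotonically with the OR's daily workload
    (rejected when the upper-segment slope is significantly positive,
    i.e. a change point exists).
    H4: duration depends on the position of the surgery in the surgeon's
    daily sequence.
    """
    t1 = model_count.table
    t2 = model_position.table

    def sig(table: pd.DataFrame, prefix: str, negative: bool | None = None) -> list[str]:
        rows = table[table.index.str.startswith(prefix)]
        hit = rows[rows["p"] < threshold]
        if negative is True:
            hit = hit[hit["estimate"] < 0]
        return list(hit.index)

    h1_terms = sig(t1, "surgery_type[") + sig(t1, "surgeon[")
    h2_terms = sig(t1, "weekday[")
    cas = t1.loc[CASELOAD]
    h3a = bool(cas["p"] < threshold and cas["estimate"] < 0)
    kink = segmented.slope_hi > 0 and not segmented.no_changepoint_flag
    h4_terms = sig(t2, "position[", negative=True)
    return {
        "threshold": threshold,
        "H1_type_and_surgeon": {"supported": bool(h1_terms), "significant_terms": h1_terms},
        "H2_weekday": {"supported": bool(h2_terms), "significant_terms": h2_terms},
        "H3a_surgeon_workload": {"supported": h3a, "coefficient": float(cas["estimate"])},
        "H3b_or_workload_monotone": {
            "supported": not kink,
            "change_point": segmented.c_hat,
            "upper_slope": segmented.slope_hi,
        },
        "H4_position": {"supported": bool(h4_terms), "significant_terms": h4_terms},
    }


@dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    features: pd.DataFrame
    segmented: SegmentedFit
    model_count: ModelFit  # main effects, continuous caseload (model I)
    model_position: ModelFit  # main effects, categorical position (model II)
    interactions: ModelFit
    lasso: LassoSelection
    profile: WorkloadProfile
    summary: pd.DataFrame  # workload/position frequency table
    verdicts: dict
    stage_log: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "n": int(len(self.features)),
            "segmented": self.segmented.to_dict(),
            "model_count": self.model_count.to_dict(),
            "model_position": self.model_position.to_dict(),
            "interactions": self.interactions.to_dict(),
            "lasso": {
                "selected": self.lasso.selected,
                "alpha": self.lasso.alpha,
                "candidates": self.lasso.candidates,
            },
            "workload_profile": self.profile.table.to_dict(orient="records"),
            "workload_summary": self.summary.to_dict(orient="records"),
            "verdicts": self.verdicts,
            "stage_log": self.stage_log,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, default=float)
        )
        (outdir / "main_effects.md").write_text(render_main_effects(self))
        (outdir / "interactions.md").write_text(render_table(self.interactions.table))
        self.profile.to_csv(outdir / "workload_profile.csv")
        pd.DataFrame({"c": self.segmented.trace}).to_csv(
            outdir / "changepoint_trace.csv", index_label="iteration"
        )


def run_pipeline(
    data: "pd.DataFrame | str | Path",
    *,
    schema_config: Mapping[str, str] | str | Path | None = None,
    lasso_seed: int = 0,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    include_anaesthetist: bool = True,
    dayfirst: bool = True,
) -> ReportBundle:
    """Run the full analysis on a schedule CSV or a prepared feature table.

    Stages: ingest -> features -> change point (estimated once on the
    continuous-caseload model, then fixed) -> both main-effects models ->
    interaction model -> LASSO selection -> workload profile and
    hypothesis verdicts.  Deterministic given the input and
    ``lasso_seed``.  A stage failure raises :class:`PipelineError` naming
    the stage.
    """
    stage_log: list[str] = []

    def stage(name, fn, *a, **kw):
        try:
            out = fn(*a, **kw)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        stage_log.append(name)
        return out

    if isinstance(data, (str, Path)):
        df, errors = stage(
            "ingest", _ingest.load_frame, data, schema_config, dayfirst=dayfirst
        )
        stage_log.append(f"ingest: {len(df)} rows kept, {len(errors)} rejected")
        if df.empty:
            raise PipelineError("stage 'ingest' failed: no valid records after validation")
    else:
        df = data
        if df.empty:
            raise PipelineError("stage 'ingest' failed: empty input table")

    if "position_label" not in df.columns:
        df = stage("features", _features.derive_features, df)
    summary = stage("features", _features.workload_summary, df)

    spec_i = model_i_spec(include_anaesthetist=include_anaesthetist)
    seg = stage("segmented", fit_segmented_iterative, df, "or_daily_n", spec_i)
    stage_log.append(f"segmented: c_hat={seg.c_hat:.3f} in {seg.n_iter} iterations")
    c = seg.c_hat

    m1 = stage(
        "model_count", fit_model, df, model_i_spec(c, include_anaesthetist=include_anaesthetist)
    )
    m2 = stage(
        "model_position",
        fit_model,
        df,
        model_ii_spec(c, include_anaesthetist=include_anaesthetist),
    )
    mi = stage(
        "interactions",
        fit_interaction_model,
        df,
        model_ii_spec(c, include_anaesthetist=include_anaesthetist),
    )
    sel = stage(
        "lasso",
        lasso_select,
        df,
        model_i_spec(c, include_anaesthetist=include_anaesthetist),
        seed=lasso_seed,
    )
    prof = stage("profile", workload_profile, df)
    verdicts = hypothesis_verdicts(m1, m2, seg, threshold=p_threshold)
    return ReportBundle(
        features=df,
        segmented=seg,
        model_count=m1,
        model_position=m2,
        interactions=mi,
        lasso=sel,
        profile=prof,
        summary=summary,
        verdicts=verdicts,
        stage_log=stage_log,
    )


# ---------------------------------------------------------------------------
# rendering


def render_table(table: pd.DataFrame, percents: pd.Series | None = None) -> str:
    """Render one coefficient table as Markdown: term, percent of cases,
    estimate, 95% CI, p and significance code."""
    lines = [
        "| Term | % | Coefficient | 95% CI | p | |",
        "|---|---|---|---|---|---|",
    ]
    for term, row in table.iterrows():
        pct = ""
        if percents is not None and term in percents.index:
            pct = f"{percents[term]:.2f}"
        p = row["p"]
        p_s = "<0.001" if p < 0.001 else f"{p:.3f}"
        lines.append(
            f"| {term} | {pct} | {row['estimate']:.3f} "
            f"| ({row['ci_low']:.3f}, {row['ci_high']:.3f}) | {p_s} | {row['code']} |"
        )
    return "\n".join(lines) + "\n"


def term_percentages(df: pd.DataFrame) -> pd.Series:
    """Percent of cases behind each categorical design term (the '%'
    column of the rendered tables), keyed by term name."""
    out: dict[str, float] = {}
    n = len(df)
    for var, col in (
        ("weekday", "weekday"),
        ("surgeon", "surgeon"),
        ("surgery_type", "surgery_type"),
        ("anaesthetist", "anaesthetist"),
        ("position", "position_label"),
    ):
        for level, cnt in df[col].value_counts().items():
            out[f"{var}[{level}]"] = cnt / n * 100.0
    return pd.Series(out)


def render_main_effects(bundle: ReportBundle) -> str:
    """Both main-effects tables plus the fit summaries, as Markdown."""
    pct = term_percentages(bundle.features)
    parts = [
        "# Main-effects models of log operative duration\n",
        f"n = {bundle.model_count.n}; "
        f"change point c = {bundle.segmented.c_hat:.2f} "
        f"(slopes {bundle.segmented.slope_lo:.3f} / {bundle.segmented.slope_hi:.3f})\n",
        "\n## Continuous surgeon caseload (model I)\n",
        render_table(bundle.model_count.table, pct),
        f"\nAdjusted R^2 = {bundle.model_count.adj_r2:.3f}\n",
        "\n## Categorical position (model II)\n",
        render_table(bundle.model_position.table, pct),
        f"\nAdjusted R^2 = {bundle.model_position.adj_r2:.3f}\n",
        "\nSignificance codes: `***` <0.001, `**` <0.01, `*` <0.05, `&` <0.1, `$` otherwise.\n",
    ]
    return "".join(parts)
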