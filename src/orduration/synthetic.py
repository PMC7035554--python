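"""Synthetic surgical-schedule generator and parameter-recovery harness.

The real schedule data this package was designed around are private, so
every stage is exercised on synthetic schedules with the same statistical
structure: roughly 2,450 thoracic operations over 34 months, six surgeons
(A the most frequent), eleven surgery types dominated by one lobectomy
type, 1-5 operations per surgeon per day, 1-6 per operating room per day,
and log-normal cut-to-suture durations with additive effects on the log
scale.

The generator works schedule-first:

1. plan surgeon-days: the number of days on which a surgeon performs k
   cases (k = 1..5) is set deterministically so the realized share of
   cases at each caseload matches the configured mix; each surgeon-day is
   then assigned a surgeon (by case share) and a calendar date (by
   weekday share, one surgeon-day per surgeon per date);
2. partition each day's cases into OR-day loads of 1-6 and hand the OR
   slots to cases at random;
3. simulate clocks: each OR's first case enters between 08:00 and 09:00,
   later cases enter after the previous case leaves plus a turnover gap;
   cases are realized in projected cut-time order so a surgeon's j-th cut
   of the day really is position ``k~j``;
4. draw ``log duration = linear predictor + Normal(0, sigma)`` and
   back-fill the suture time; durations are rounded to whole minutes
   (minute-resolution clocks).

Generated datasets always pass ingest validation, and the sidecar truth
dictionary records every generating parameter so recovery experiments can
score bias, RMSE and confidence-interval coverage per coefficient.
"""

from __future__ import annotations

import datetime as dt
import heapq
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import features as _features
from . import ingest as _ingest
from .ingest import SurgeryRecord
from .models import CASELOAD, HINGE_HI, HINGE_LO, ModelSpec, model_i_spec
from .segmented import fit_segmented_iterative

log = logging.getLogger(__name__)


class GenerationError(ValueError):
    """The configuration cannot produce a feasible schedule."""


#: the eleven surgery types with their case shares and log-scale effects
#: (reference first; effects are relative to the reference type)
DEFAULT_TYPES: tuple[tuple[str, float, float], ...] = (
    ("Thoracoscopic interior pulmonary lobectomy", 0.3795, 0.0),
    ("Lung cancer", 0.0404, 0.155),
    ("Thoracoscopic pulmonary bullous resection", 0.0249, -0.369),
    ("Thoracoscopic partial pulmonary lobectomy", 0.1807, 0.009),
    ("Total pneumonectomy", 0.0110, 0.388),
    ("Partial pulmonary lobectomy", 0.1142, 0.110),
    ("Thoracoscopic exploration", 0.0131, 0.031),
    ("Pulmonary wedge resection", 0.0237, -0.077),
    ("Esophageal cancer", 0.0204, 0.774),
    ("Mediastinal tumor resection", 0.0579, -0.170),
    ("Pulmonary tumor resection", 0.1342, -0.043),
)

DEFAULT_SURGEON_SHARES: dict[str, float] = {
    "A": 0.3748,
    "B": 0.2069,
    "C": 0.1975,
    "D": 0.1208,
    "E": 0.0694,
    "F": 0.0306,
}

DEFAULT_SURGEON_EFFECTS: dict[str, float] = {
    "A": 0.0,
    "B": -0.094,
    "C": 0.058,
    "D": -0.006,
    "E": -0.034,
    "F": -0.272,
}

DEFAULT_WEEKDAY_SHARES: dict[str, float] = {
    "Sun": 0.0122,
    "Mon": 0.0180,
    "Tue": 0.2077,
    "Wed": 0.2003,
    "Thu": 0.1775,
    "Fri": 0.2297,
    "Sat": 0.1546,
}

DEFAULT_WEEKDAY_EFFECTS: dict[str, float] = {
    "Sun": -0.041,
    "Mon": -0.065,
    "Tue": 0.056,
    "Wed": 0.033,
    "Thu": 0.007,
    "Fri": 0.054,
    "Sat": 0.0,
}

#: position effects relative to a surgeon's only case of the day ("1~1")
DEFAULT_POSITION_EFFECTS: dict[str, float] = {
    "2~1": -0.075,
    "2~2": -0.067,
    "3~1": -0.169,
    "3~2": -0.145,
    "3~3": -0.163,
    "4~1": -0.206,
    "4~2": -0.141,
    "4~3": -0.129,
    "4~4": -0.148,
    "5~1": -0.287,
    "5~2": -0.051,
    "5~3": -0.132,
    "5~4": -0.443,
    "5~5": -0.105,
}

DEFAULT_ANAESTHETIST_SHARES: dict[str, float] = {
    "AN1": 0.28,
    "AN2": 0.20,
    "AN3": 0.16,
    "AN4": 0.12,
    "AN5": 0.10,
    "AN6": 0.08,
    "AN7": 0.06,
}

#: share of cases whose surgeon performs k cases that day, k = 1..5
DEFAULT_CASELOAD_MIX: tuple[float, ...] = (0.2493, 0.3986, 0.2497, 0.0906, 0.0118)

#: share of cases in an OR running m cases that day, m = 1..6; the busy
#: levels 5-6 are uncommon, which is what makes their profile CIs wide
DEFAULT_OR_LOAD_MIX: tuple[float, ...] = (0.08, 0.20, 0.30, 0.27, 0.09, 0.06)


@dataclass
class SyntheticConfig:
    """All generator knobs.  Same seed + config gives byte-identical
    output.

    Effects are on the natural-log scale (log minutes).  ``mode`` selects
    which surgeon-workload truth enters the linear predictor: ``"linear"``
    uses ``caseload_slope * k`` (the continuous-count model's truth),
    ``"position"`` uses the per-label ``position_effects`` (the
    position-model's truth).  The two parameterizations are collinear, so
    a single dataset can only embody one of them.
    """

    seed: int = 7
    n_target: int = 2451
    start_date: dt.date = dt.date(2014, 1, 1)
    months: int = 34
    surgeon_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SURGEON_SHARES)
    )
    surgeon_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SURGEON_EFFECTS)
    )
    caseload_mix: tuple[float, ...] = DEFAULT_CASELOAD_MIX
    or_load_mix: tuple[float, ...] = DEFAULT_OR_LOAD_MIX
    n_ors: int = 15
    types: tuple[tuple[str, float, float], ...] = DEFAULT_TYPES
    weekday_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEEKDAY_SHARES)
    )
    weekday_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEEKDAY_EFFECTS)
    )
    anaesthetist_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANAESTHETIST_SHARES)
    )
    anaesthetist_effects: dict[str, float] = field(default_factory=dict)
    intercept: float = 4.97
    hinge_slope_lo: float = -0.067
    hinge_slope_hi: float = 0.109
    breakpoint: float = 4.0
    caseload_slope: float = -0.061
    position_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POSITION_EFFECTS)
    )
    interaction_effects: dict[str, float] = field(default_factory=dict)
    #: keys of interaction_effects are "surgeon:position", e.g. "B:4~3"
    mode: str = "linear"  # "linear" | "position"
    sigma: float = 0.45
    turnover_min: int = 30
    first_case_window: tuple[int, int] = (8 * 60, 9 * 60)  # minutes of day
    same_or_per_surgeon: bool = False

    def __post_init__(self) -> None:
        for name, w in (
            ("caseload_mix", self.caseload_mix),
            ("or_load_mix", self.or_load_mix),
            ("surgeon_shares", tuple(self.surgeon_shares.values())),
            ("weekday_shares", tuple(self.weekday_shares.values())),
            ("anaesthetist_shares", tuple(self.anaesthetist_shares.values())),
            ("type shares", tuple(t[1] for t in self.types)),
        ):
            w = np.asarray(w, dtype=float)
            if np.any(w < 0):
                raise GenerationError(f"{name}: negative weight")
            if abs(w.sum() - 1.0) > 1e-6:
                raise GenerationError(f"{name}: weights sum to {w.sum()}, not 1")
        if self.mode not in ("linear", "position"):
            raise GenerationError(f"unknown mode {self.mode!r}")
        if self.sigma < 0:
            raise GenerationError("sigma must be >= 0")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if isinstance(d.get("start_date"), str):
            d["start_date"] = dt.date.fromisoformat(d["start_date"])
        for key in ("caseload_mix", "or_load_mix", "first_case_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "types" in d:
            d["types"] = tuple(tuple(t) for t in d["types"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def null_config(sigma: float = 0.0, seed: int = 7, **kw) -> SyntheticConfig:
    """A degenerate configuration with every effect zero.

    With ``sigma=0`` every generated duration is ``exp(intercept)``
    rounded to the minute; useful for exact-limit checks.
    """
    return SyntheticConfig(
        seed=seed,
        sigma=sigma,
        surgeon_effects={k: 0.0 for k in DEFAULT_SURGEON_SHARES},
        weekday_effects={k: 0.0 for k in DEFAULT_WEEKDAY_SHARES},
        types=tuple((n, s, 0.0) for n, s, _ in DEFAULT_TYPES),
        hinge_slope_lo=0.0,
        hinge_slope_hi=0.0,
        caseload_slope=0.0,
        position_effects={k: 0.0 for k in DEFAULT_POSITION_EFFECTS},
        **kw,
    )


def _calendar(cfg: SyntheticConfig) -> list[dt.date]:
    y, m = cfg.start_date.year, cfg.start_date.month
    m_end = m + cfg.months  # first day after the window
    y_end, m_end = y + (m_end - 1) // 12, (m_end - 1) % 12 + 1
    end = dt.date(y_end, m_end, 1)
    days = []
    d = cfg.start_date
    while d < end:
        days.append(d)
        d += dt.timedelta(days=1)
    return days


def _plan_surgeon_days(cfg: SyntheticConfig) -> list[int]:
    """Deterministic counts of surgeon-days at each caseload so realized
    case shares match ``caseload_mix``."""
    p = np.asarray(cfg.caseload_mix, dtype=float)
    ks = np.arange(1, len(p) + 1)
    q = (p / ks) / (p / ks).sum()  # surgeon-day-level distribution
    d_total = cfg.n_target / float((q * ks).sum())
    n_days = np.maximum(np.round(q * d_total), 0).astype(int)
    diff = cfg.n_target - int((n_days * ks).sum())
    # absorb the rounding remainder in 1-case days
    n_days[0] = max(n_days[0] + diff, 0)
    loads: list[int] = []
    for k, n in zip(ks, n_days):
        loads.extend([int(k)] * int(n))
    return loads


def truth_coefficients(cfg: SyntheticConfig, workload_form: str | None = None) -> dict[str, float]:
    """Generating coefficients keyed by the design-matrix term names of
    :func:`orduration.models.build_design` (workload form per ``cfg.mode``
    unless overridden)."""
    form = workload_form or ("count" if cfg.mode == "linear" else "position")
    out: dict[str, float] = {"const": cfg.intercept}
    for wd, eff in cfg.weekday_effects.items():
        if wd != "Sat":
            out[f"weekday[{wd}]"] = eff
    out[HINGE_LO] = cfg.hinge_slope_lo
    out[HINGE_HI] = cfg.hinge_slope_hi
    if form == "count":
        out[CASELOAD] = cfg.caseload_slope
    else:
        for lab, eff in cfg.position_effects.items():
            out[f"position[{lab}]"] = eff
    for s in cfg.surgeon_shares:
        if s != "A":
            out[f"surgeon[{s}]"] = cfg.surgeon_effects.get(s, 0.0)
    for name, _, eff in cfg.types[1:]:
        out[f"surgery_type[{name}]"] = eff
    for a in cfg.anaesthetist_shares:
        ref = max(cfg.anaesthetist_shares, key=cfg.anaesthetist_shares.get)
        if a != ref:
            out[f"anaesthetist[{a}]"] = cfg.anaesthetist_effects.get(a, 0.0)
    return out


def _linear_predictor(
    cfg: SyntheticConfig,
    weekday: str,
    surgeon: str,
    stype: str,
    anaesthetist: str,
    or_n: int,
    k: int,
    j: int,
) -> float:
    type_effects = {t[0]: t[2] for t in cfg.types}
    lp = cfg.intercept
    lp += cfg.weekday_effects.get(weekday, 0.0)
    lp += cfg.surgeon_effects.get(surgeon, 0.0)
    lp += type_effects[stype]
    lp += cfg.anaesthetist_effects.get(anaesthetist, 0.0)
    lp += cfg.hinge_slope_lo * min(or_n, cfg.breakpoint)
    lp += cfg.hinge_slope_hi * max(or_n - cfg.breakpoint, 0.0)
    if cfg.mode == "linear":
        lp += cfg.caseload_slope * k
    else:
        lp += cfg.position_effects.get(f"{k}~{j}", 0.0)
        lp += cfg.interaction_effects.get(f"{surgeon}:{k}~{j}", 0.0)
    return lp


def generate_dataset(
    cfg: SyntheticConfig | None = None,
) -> tuple[list[SurgeryRecord], dict]:
    """Generate one synthetic schedule.

    Returns the records (which satisfy all ingest invariants) and a truth
    dictionary holding the full configuration plus the generating
    coefficients keyed by design-matrix term name.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    days = _calendar(cfg)
    wd_counts = pd.Series([_ingest.WEEKDAYS[d.weekday()] for d in days]).value_counts()
    day_w = np.array(
        [cfg.weekday_shares[_ingest.WEEKDAYS[d.weekday()]] / wd_counts[_ingest.WEEKDAYS[d.weekday()]] for d in days]
    )
    day_w = day_w / day_w.sum()

    # 1. surgeon-days -> (surgeon, date, k)
    loads = _plan_surgeon_days(cfg)
    rng.shuffle(loads)
    surgeons = list(cfg.surgeon_shares)
    s_w = np.array([cfg.surgeon_shares[s] for s in surgeons])
    s_w = s_w / s_w.sum()
    taken: set[tuple[str, int]] = set()
    plan: dict[dt.date, list[tuple[str, int]]] = {}
    for k in loads:
        s = surgeons[rng.choice(len(surgeons), p=s_w)]
        for _ in range(200):
            di = int(rng.choice(len(days), p=day_w))
            if (s, di) not in taken:
                break
        else:  # fall back to any free day for this surgeon
            free = [i for i in range(len(days)) if (s, i) not in taken]
            if not free:
                raise GenerationError("calendar exhausted: too many surgeon-days")
            di = int(rng.choice(free))
        taken.add((s, di))
        plan.setdefault(days[di], []).append((s, k))

    # 2./3. per day: OR partition + clock simulation
    or_pool = [f"OR{i + 1:02d}" for i in range(cfg.n_ors)]
    m_max = len(cfg.or_load_mix)
    s_mix = np.asarray(cfg.or_load_mix, dtype=float)
    # greedy deficit tracking so the realized case share at each OR-day
    # load follows the configured mix despite the day-total constraint
    or_assigned = np.zeros(m_max)
    or_assigned_total = 0.0
    type_names = [t[0] for t in cfg.types]
    type_w = np.array([t[1] for t in cfg.types])
    an_names = list(cfg.anaesthetist_shares)
    an_w = np.array(list(cfg.anaesthetist_shares.values()))
    an_w = an_w / an_w.sum()

    records: list[SurgeryRecord] = []
    ridx = 0
    for day in sorted(plan):
        case_surgeons: list[tuple[str, int]] = []  # (surgeon, k) per case
        for s, k in plan[day]:
            case_surgeons.extend([(s, k)] * k)
        total = len(case_surgeons)
        if total > cfg.n_ors * m_max:
            raise GenerationError(
                f"{day}: {total} cases exceed OR capacity {cfg.n_ors * m_max}"
            )
        # partition into OR loads: pick the load whose assignment moves the
        # realized case-share mix closest to the configured one
        or_loads: list[int] = []
        remaining = total
        while remaining > 0:
            if len(or_loads) == cfg.n_ors - 1:
                if remaining > m_max:
                    raise GenerationError(
                        f"{day}: cannot place {remaining} remaining cases in one OR"
                    )
                m = remaining
            else:
                feas = range(1, min(remaining, m_max) + 1)
                errs = []
                for m_c in feas:
                    a = or_assigned.copy()
                    a[m_c - 1] += m_c
                    share = a / (or_assigned_total + m_c)
                    errs.append(float(((share - s_mix) ** 2).sum()))
                jitter = rng.uniform(0, 1e-9, size=len(errs))
                m = int(np.argmin(np.asarray(errs) + jitter)) + 1
            or_assigned[m - 1] += m
            or_assigned_total += m
            or_loads.append(m)
            remaining -= m
        or_ids = list(rng.choice(or_pool, size=len(or_loads), replace=False))
        order = rng.permutation(total)
        queues: list[list[tuple[str, int]]] = []
        pos = 0
        for m in or_loads:
            queues.append([case_surgeons[i] for i in order[pos : pos + m]])
            pos += m

        # event loop in projected cut-time order
        heap: list[tuple[int, int]] = []  # (projected t_cut, or index)
        ready = [int(rng.integers(*cfg.first_case_window)) for _ in or_loads]
        gaps1 = rng.integers(10, 21, size=total)  # enter -> anaesthesia
        gaps2 = rng.integers(20, 51, size=total)  # anaesthesia -> cut
        gaps3 = rng.integers(8, 19, size=total)  # sew -> leave
        noise = rng.normal(0.0, cfg.sigma, size=total)
        gi = 0
        gap_of: dict[int, tuple[int, int, int, float]] = {}
        nexti = [0] * len(or_loads)

        def push(oi: int) -> None:
            nonlocal gi
            if nexti[oi] >= or_loads[oi]:
                return
            g = (int(gaps1[gi]), int(gaps2[gi]), int(gaps3[gi]), float(noise[gi]))
            gi += 1
            t_enter = ready[oi]
            t_cut = t_enter + g[0] + g[1]
            gap_of[oi] = g
            heapq.heappush(heap, (t_cut, oi))

        for oi in range(len(or_loads)):
            push(oi)
        served: dict[str, int] = {}
        used_cuts: dict[str, set[int]] = {}
        weekday = _ingest.WEEKDAYS[day.weekday()]
        while heap:
            t_cut, oi = heapq.heappop(heap)
            g1, g2, g3, eps = gap_of[oi]
            s, k = queues[oi][nexti[oi]]
            # keep a surgeon's cut times distinct within the day
            cuts = used_cuts.setdefault(s, set())
            while t_cut in cuts:
                t_cut += 1
            cuts.add(t_cut)
            j = served.get(s, 0) + 1
            served[s] = j
            or_n = or_loads[oi]
            stype = type_names[rng.choice(len(type_names), p=type_w)]
            an = an_names[rng.choice(len(an_names), p=an_w)]
            lp = _linear_predictor(cfg, weekday, s, stype, an, or_n, k, j)
            duration = max(1, int(round(np.exp(lp + eps))))
            t_enter = t_cut - g1 - g2
            t_anaes = t_enter + g1
            t_sew = t_cut + duration
            t_leave = t_sew + g3
            ridx += 1
            records.append(
                SurgeryRecord(
                    record_id=f"R{ridx:05d}",
                    sex="M" if rng.random() < 0.55 else "F",
                    age=int(np.clip(round(rng.normal(55, 13)), 16, 90)),
                    date=day,
                    or_id=str(or_ids[oi]),
                    surgeon=s,
                    surgery_type=stype,
                    anaesthetist=an,
                    t_enter=_minutes_to_time(t_enter),
                    t_anaesthesia=_minutes_to_time(t_anaes),
                    t_cut=_minutes_to_time(t_cut),
                    t_sew=_minutes_to_time(t_sew),
                    t_leave=_minutes_to_time(t_leave),
                )
            )
            nexti[oi] += 1
            ready[oi] = t_leave + cfg.turnover_min
            push(oi)

    truth = {
        "config": cfg.to_dict(),
        "coefficients": truth_coefficients(cfg),
        "sigma": cfg.sigma,
        "breakpoint": cfg.breakpoint,
        "hinge_slopes": [cfg.hinge_slope_lo, cfg.hinge_slope_hi],
        "n": len(records),
    }
    return records, truth


def _minutes_to_time(m: int) -> dt.time:
    return dt.time((m // 60) % 24, m % 60)


def generate_frame(cfg: SyntheticConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Generate a schedule and run it through the outcome and feature
    stages; returns the analysis-ready feature table plus the truth."""
    records, truth = generate_dataset(cfg)
    durs, errs = _ingest.compute_durations(records)
    if errs:  # the generator contracts to emit only valid records
        raise GenerationError(f"generator produced invalid records: {errs[:3]}")
    return _features.derive_features(_ingest.records_to_frame(durs)), truth


def write_dataset(
    cfg: SyntheticConfig, csv_path: str | Path, truth_path: str | Path | None = None
) -> dict:
    """Generate and persist a schedule as canonical CSV plus a JSON truth
    sidecar; returns the truth dictionary."""
    records, truth = generate_dataset(cfg)
    _ingest.write_records(records, csv_path)
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=2))
    return truth


# ---------------------------------------------------------------------------
# parameter recovery


@dataclass
class RecoveryReport:
    """Per-coefficient recovery metrics over generated replicates."""

    table: pd.DataFrame  # index term; truth, mean_estimate, bias, rmse, coverage
    c_hats: list[float]
    n_replicates: int
    n_failures: int
    failures: list[str]

    @property
    def mean_c_hat(self) -> float:
        return float(np.mean(self.c_hats)) if self.c_hats else float("nan")


def recovery_experiment(
    cfg: SyntheticConfig | None = None,
    n_replicates: int = 100,
    *,
    estimate_breakpoint: bool = True,
    workload_form: str | None = None,
) -> RecoveryReport:
    """Generate -> ingest -> features -> change point -> model, repeatedly,
    and score how well the generating coefficients are recovered.

    Each replicate re-generates a dataset from a child seed of
    ``cfg.seed``, estimates the breakpoint (the distribution of ``c_hat``
    scores knot recovery), fits the main-effects model matching the
    generator's truth parameterization, and records each coefficient's
    estimate and whether its 95% CI covers the generating value.  The
    scored model is fitted at the generating knot: hinge slopes at
    different knots are different estimands, so calibration of the slope
    CIs is only meaningful at the knot the effects were generated with.
    Per-replicate failures are recorded, not raised.
    """
    cfg = cfg or SyntheticConfig()
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    form = workload_form or ("count" if cfg.mode == "linear" else "position")
    truth = truth_coefficients(cfg, form)
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    est_rows: list[pd.Series] = []
    cover_rows: list[pd.Series] = []
    c_hats: list[float] = []
    failures: list[str] = []
    for rep, s in enumerate(seeds):
        try:
            df, _ = generate_frame(replace(cfg, seed=int(s)))
            spec = ModelSpec(workload_form=form, breakpoint=cfg.breakpoint)
            if estimate_breakpoint:
                seg = fit_segmented_iterative(df, "or_daily_n", spec)
                c_hats.append(seg.c_hat)
            from .models import fit_model

            fit = fit_model(df, spec)
            t = fit.table
            tv = pd.Series(truth)
            common = t.index.intersection(tv.index)
            est_rows.append(t["estimate"])
            cover_rows.append(
                (t.loc[common, "ci_low"] <= tv[common])
                & (tv[common] <= t.loc[common, "ci_high"])
            )
        except Exception as exc:  # per-replicate failure is data, not fatal
            failures.append(f"replicate {rep}: {exc!r}")
    if not est_rows:
        raise RuntimeError(f"all {n_replicates} replicates failed: {failures[:3]}")
    est = pd.DataFrame(est_rows)
    cover = pd.DataFrame(cover_rows)
    terms = [t for t in est.columns if t in truth]
    tv = pd.Series(truth)[terms]
    table = pd.DataFrame(
        {
            "truth": tv,
            "mean_estimate": est[terms].mean(),
            "bias": est[terms].mean() - tv,
            "rmse": np.sqrt(((est[terms] - tv) ** 2).mean()),
            "coverage": cover[terms].mean(),
        }
    )
    return RecoveryReport(
        table=table,
        c_hats=c_hats,
        n_replicates=n_replicates,
        n_failures=len(failures),
        failures=failures,
    )
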