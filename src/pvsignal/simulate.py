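"""Synthetic spontaneous-reporting databases.

Real ICSR databases (VigiBase, FAERS, EudraVigilance) are access-restricted,
so every stage of the screening pipeline is exercised against generated data
with the statistical structure the case/non-case design assumes:

* each report is independently exposed to each drug class with the class's
  exposure prevalence (the fraction of database reports carrying a suspect
  drug of that class);
* the target event is reported with probability
  ``background_event_prob * max(rr over the report's exposed classes)``
  (1 if unexposed) — a multiplicative relative reporting rate, the simplest
  mechanism whose induced ROR approaches the injected rr for a rare event;
* demographics, onset lags, seriousness and outcomes are drawn from
  configurable marginal distributions, independent of exposure.

Two generation paths share the same random draws: a materialized path that
builds full :class:`~pvsignal.icsr.ICSReport` objects, and a counts-only
path (:func:`simulate_tables`) that tallies the per-class 2x2 tables
directly, used for replicated operating-characteristic studies where
materializing millions of reports would be pointless.

A third, deterministic constructor (:func:`generate_tabulated` /
:func:`tabulate_virtual`) reconstructs a database from explicit per-class
(a, b) counts and totals, e.g. the printed counts of a published screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .casenoncase import TermSelector, TwoByTwoTable
from .disproportionality import SignalTable, screen_signals, screen_tables
from .icsr import (
    ClassMap,
    DrugEntry,
    EventTerm,
    ICSReport,
    Outcome,
    ParameterError,
    ReportSet,
    Role,
    Seriousness,
    Sex,
)

__all__ = [
    "ClassSpec",
    "SimConfig",
    "OperatingCharacteristics",
    "make_class_map",
    "generate_reports",
    "simulate_tables",
    "generate_tabulated",
    "tabulate_virtual",
    "evaluate_operating_characteristics",
    "null_config",
    "power_config",
]

_EPOCH = date(2015, 1, 1)
_WINDOW_DAYS = (date(2021, 12, 31) - _EPOCH).days  # administration window

DEFAULT_TARGET_CODE = "LLT0001"
DEFAULT_TARGET_NAME = "Anti-NMDA receptor encephalitis"
OTHER_EVENT = EventTerm("EVT_OTHER", "Other reaction")
OTHER_DRUG_NAME = "other medicinal product"
OTHER_CLASS = "OTHER"


@dataclass
class ClassSpec:
    """One simulated drug class.

    exposure_prevalence: probability a report carries a suspect drug of the
    class.  rr: relative reporting rate of the target event given exposure
    (1 = null).  pediatric_fraction and the two age medians shape the
    age mixture of exposed reports (child/adult log-normal components).
    """

    class_id: str
    exposure_prevalence: float
    rr: float = 1.0
    label: Optional[str] = None
    pediatric_fraction: float = 0.5
    age_child_median: float = 10.0
    age_adult_median: float = 35.0


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic reporting database.

    Defaults emulate a spontaneous-reporting database with a rare
    neurological target event: background reporting probability a few per
    million reports, a log-normal onset lag with median 4 days capped at
    730 days, mostly-female case mix and a seriousness/outcome profile
    typical of serious CNS adverse-event reports.
    """

    n_reports: int
    seed: int = 0
    classes: list[ClassSpec] = field(default_factory=list)
    background_event_prob: float = 2.4e-6
    target_term_code: str = DEFAULT_TARGET_CODE
    target_term_name: str = DEFAULT_TARGET_NAME
    sex_female_prob: float = 0.56
    sex_unknown_prob: float = 0.05
    age_missing_prob: float = 0.10
    background_age_median: float = 50.0
    age_sigma: float = 0.5
    country_weights: dict[str, float] = field(
        default_factory=lambda: {"JP": 0.345, "FR": 0.172, "GB": 0.172, "US": 0.311}
    )
    onset_lag_median: float = 4.0
    onset_lag_sigma: float = 1.6
    onset_lag_max: int = 730
    serious_prob: float = 0.4
    seriousness_weights: dict[str, float] = field(
        # proportions mirroring a serious CNS case-series profile
        default_factory=lambda: {
            "death": 0.034,
            "life_threatening": 0.104,
            "hospitalization": 0.552,
            "disabling": 0.138,
            "other_medically_important": 0.172,
        }
    )
    outcome_weights: dict[str, float] = field(
        default_factory=lambda: {
            "recovered": 0.155,
            "recovering": 0.155,
            "not_recovered_or_sequelae": 0.448,
            "fatal": 0.035,
            "unknown": 0.207,
        }
    )

    def validate(self) -> list[str]:
        v: list[str] = []
        if self.n_reports < 0:
            v.append("n_reports must be >= 0")
        if not 0 <= self.background_event_prob <= 1:
            v.append("background_event_prob must be in [0, 1]")
        seen: set[str] = set()
        for c in self.classes:
            if not 0 <= c.exposure_prevalence <= 1:
                v.append(f"class {c.class_id}: exposure_prevalence must be in [0, 1]")
            if c.rr < 0:
                v.append(f"class {c.class_id}: rr must be >= 0")
            if not 0 <= c.pediatric_fraction <= 1:
                v.append(f"class {c.class_id}: pediatric_fraction must be in [0, 1]")
            if c.class_id in seen:
                v.append(f"duplicate class_id {c.class_id}")
            seen.add(c.class_id)
        for name in ("sex_female_prob", "sex_unknown_prob", "age_missing_prob",
                     "serious_prob"):
            if not 0 <= getattr(self, name) <= 1:
                v.append(f"{name} must be in [0, 1]")
        for wname in ("country_weights", "seriousness_weights", "outcome_weights"):
            w = getattr(self, wname)
            if not w or any(x < 0 for x in w.values()) or sum(w.values()) <= 0:
                v.append(f"{wname} must be non-empty with non-negative weights")
        if self.onset_lag_median <= 0 or self.onset_lag_sigma <= 0:
            v.append("onset lag median and sigma must be positive")
        return v

    @property
    def is_null(self) -> bool:
        return all(c.rr == 1 for c in self.classes)

    @property
    def target_selector(self) -> TermSelector:
        return TermSelector(term_code=self.target_term_code)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        classes = [ClassSpec(**c) for c in doc.pop("classes", [])]
        return cls(classes=classes, **doc)

    def to_file(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _check(cfg: SimConfig) -> None:
    violations = cfg.validate()
    if violations:
        raise ParameterError("invalid SimConfig: " + "; ".join(violations))


def make_class_map(cfg: SimConfig) -> ClassMap:
    """Class map covering the simulated classes plus the catch-all class."""
    labels = {c.class_id: (c.label or c.class_id) for c in cfg.classes}
    labels[OTHER_CLASS] = "Other drugs"
    entries = {f"{c.class_id} vaccine": c.class_id for c in cfg.classes}
    entries[OTHER_DRUG_NAME] = OTHER_CLASS
    return ClassMap(entries=entries, labels=labels)


# ---------------------------------------------------------------------------
# Core draws (shared by both generation paths)
# ---------------------------------------------------------------------------


def _draw_exposure_and_cases(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exposure matrix (n_reports x n_classes, bool) and case indicator."""
    n, k = cfg.n_reports, len(cfg.classes)
    if k == 0:
        return np.zeros((n, 0), dtype=bool), rng.random(n) < cfg.background_event_prob
    prev = np.array([c.exposure_prevalence for c in cfg.classes])
    rr = np.array([c.rr for c in cfg.classes])
    exposed = rng.random((n, k)) < prev
    rr_eff = np.where(exposed, rr, 1.0).max(axis=1, initial=1.0)
    p_event = np.clip(cfg.background_event_prob * rr_eff, 0.0, 1.0)
    case = rng.random(n) < p_event
    return exposed, case


def simulate_tables(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, TwoByTwoTable]:
    """Counts-only generation: per-class 2x2 tables tallied directly from
    the exposure/event draws, identical (same seed) to tallying the
    materialized reports."""
    _check(cfg)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    exposed, case = _draw_exposure_and_cases(cfg, rng)
    n_cases = int(case.sum())
    n = cfg.n_reports
    out = {}
    for j, spec in enumerate(cfg.classes):
        a = int((exposed[:, j] & case).sum())
        b = int(exposed[:, j].sum()) - a
        out[spec.class_id] = TwoByTwoTable(
            a, b, n_cases - a, n - n_cases - b,
            class_id=spec.class_id, term_code=cfg.target_term_code,
        )
    return out


# ---------------------------------------------------------------------------
# Materialized generation
# ---------------------------------------------------------------------------


def _lognormal_ages(
    rng: np.random.Generator, medians: np.ndarray, sigma: float
) -> np.ndarray:
    return np.clip(
        np.exp(np.log(medians) + sigma * rng.standard_normal(medians.shape)), 0.0, 110.0
    )


def generate_reports(cfg: SimConfig) -> ReportSet:
    """Materialize a full synthetic :class:`ReportSet` (deterministic given
    the config seed)."""
    _check(cfg)
    rng = np.random.default_rng(cfg.seed)
    exposed, case = _draw_exposure_and_cases(cfg, rng)
    n, k = cfg.n_reports, len(cfg.classes)

    # vectorized attribute draws
    sex_u = rng.random(n)
    age_missing = rng.random(n) < cfg.age_missing_prob
    # per-report age medians: first exposed class's mixture, else background
    medians = np.full(n, cfg.background_age_median)
    child = rng.random(n)
    for j in reversed(range(k)):
        spec = cfg.classes[j]
        m = np.where(
            child < spec.pediatric_fraction, spec.age_child_median, spec.age_adult_median
        )
        medians = np.where(exposed[:, j], m, medians)
    ages = _lognormal_ages(rng, medians, cfg.age_sigma)

    countries = list(cfg.country_weights)
    cw = np.array(list(cfg.country_weights.values()), dtype=float)
    country_idx = rng.choice(len(countries), size=n, p=cw / cw.sum())

    admin_offsets = rng.integers(0, _WINDOW_DAYS + 1, size=(n, max(k, 1)))
    lags = np.minimum(
        np.round(
            np.exp(
                np.log(cfg.onset_lag_median)
                + cfg.onset_lag_sigma * rng.standard_normal(n)
            )
        ).astype(int),
        cfg.onset_lag_max,
    )

    serious = rng.random(n) < cfg.serious_prob
    ser_cats = list(cfg.seriousness_weights)
    sw = np.array(list(cfg.seriousness_weights.values()), dtype=float)
    ser_idx = rng.choice(len(ser_cats), size=n, p=sw / sw.sum())
    out_cats = list(cfg.outcome_weights)
    ow = np.array(list(cfg.outcome_weights.values()), dtype=float)
    out_idx = rng.choice(len(out_cats), size=n, p=ow / ow.sum())

    width = len(str(max(n, 1)))
    reports: list[ICSReport] = []
    for i in range(n):
        drugs: list[DrugEntry] = []
        latest_admin: Optional[date] = None
        for j in range(k):
            if exposed[i, j]:
                spec = cfg.classes[j]
                admin = _EPOCH + timedelta(days=int(admin_offsets[i, j]))
                drugs.append(
                    DrugEntry(
                        f"{spec.class_id} vaccine",
                        Role.suspect,
                        spec.class_id,
                        admin,
                    )
                )
                if latest_admin is None or admin > latest_admin:
                    latest_admin = admin
        if not drugs:
            drugs.append(DrugEntry(OTHER_DRUG_NAME, Role.suspect, OTHER_CLASS))
        if case[i]:
            onset = (
                latest_admin + timedelta(days=int(lags[i]))
                if latest_admin is not None
                else _EPOCH + timedelta(days=int(admin_offsets[i, 0]))
            )
            events = (
                EventTerm(cfg.target_term_code, cfg.target_term_name, onset),
            )
        else:
            events = (OTHER_EVENT,)
        if sex_u[i] < cfg.sex_unknown_prob:
            sex = Sex.unknown
        elif sex_u[i] < cfg.sex_unknown_prob + (1 - cfg.sex_unknown_prob) * cfg.sex_female_prob:
            sex = Sex.female
        else:
            sex = Sex.male
        reports.append(
            ICSReport(
                report_id=f"R{i:0{width}d}",
                drugs=tuple(drugs),
                events=events,
                age_years=None if age_missing[i] else round(float(ages[i]), 1),
                sex=sex,
                country=countries[country_idx[i]],
                seriousness=(
                    frozenset({Seriousness(ser_cats[ser_idx[i]])})
                    if serious[i]
                    else frozenset()
                ),
                outcome=Outcome(out_cats[out_idx[i]]),
            )
        )
    return ReportSet(
        reports,
        extraction_date=date(2021, 12, 31),
        metadata={"generator": "pvsignal.simulate", "seed": cfg.seed},
    )


# ---------------------------------------------------------------------------
# Reconstruction from explicit counts
# ---------------------------------------------------------------------------


def _check_counts(
    counts: dict[str, tuple[int, int]], n_cases: int, n_reports: int,
    n_exposed_cases: Optional[int],
) -> int:
    n_noncases = n_reports - n_cases
    if n_cases < 0 or n_noncases < 0:
        raise ParameterError("need 0 <= n_cases <= n_reports")
    max_a = 0
    sum_a = 0
    for cid, (a, b) in counts.items():
        if a < 0 or b < 0:
            raise ParameterError(f"class {cid}: counts must be non-negative")
        if a > n_cases:
            raise ParameterError(
                f"class {cid}: a={a} exceeds n_cases={n_cases}"
            )
        if b > n_noncases:
            raise ParameterError(
                f"class {cid}: b={b} exceeds n_noncases={n_noncases}"
            )
        max_a = max(max_a, a)
        sum_a += a
    m = n_exposed_cases if n_exposed_cases is not None else min(sum_a, n_cases)
    if sum_a and not (max_a <= m <= min(sum_a, n_cases)):
        raise ParameterError(
            f"n_exposed_cases={m} infeasible: must be in "
            f"[{max_a}, {min(sum_a, n_cases)}]"
        )
    return m


def tabulate_virtual(
    counts: dict[str, tuple[int, int]],
    n_cases: int,
    n_reports: int,
    term_code: str = DEFAULT_TARGET_CODE,
) -> dict[str, TwoByTwoTable]:
    """Per-class 2x2 tables implied by explicit (a, b) counts and totals,
    without materializing any report (c = n_cases - a; d = rest)."""
    _check_counts(counts, n_cases, n_reports, None)
    return {
        cid: TwoByTwoTable(
            a, b, n_cases - a, n_reports - n_cases - b,
            class_id=cid, term_code=term_code,
        )
        for cid, (a, b) in counts.items()
    }


def generate_tabulated(
    counts: dict[str, tuple[int, int]],
    n_cases: int,
    n_reports: int,
    n_exposed_cases: Optional[int] = None,
    term_code: str = DEFAULT_TARGET_CODE,
    term_name: str = DEFAULT_TARGET_NAME,
) -> ReportSet:
    """Minimal materialized ReportSet whose tallied contingency tables
    reproduce the given per-class (a, b) counts exactly.

    Class exposures among cases are spread least-loaded-first over the
    first ``n_exposed_cases`` case reports (default: min(sum of a, n_cases)),
    so multi-class case reports absorb any excess of sum(a) over the number
    of vaccine-involved cases.  Suspect-drug mentions per class therefore
    equal the class's a count.  Infeasible specifications raise
    :class:`~pvsignal.icsr.ParameterError` naming the violated constraint.
    """
    m = _check_counts(counts, n_cases, n_reports, n_exposed_cases)
    n_noncases = n_reports - n_cases
    cw = len(str(max(n_cases, 1)))
    nw = len(str(max(n_noncases, 1)))

    # least-loaded assignment of per-class case exposures
    case_classes: list[list[str]] = [[] for _ in range(n_cases)]
    if m > 0:
        loads = np.zeros(m, dtype=int)
        for cid, (a, _b) in sorted(
            counts.items(), key=lambda kv: -kv[1][0]
        ):
            if a == 0:
                continue
            order = np.argsort(loads, kind="stable")[:a]
            for i in order:
                case_classes[int(i)].append(cid)
            loads[order] += 1

    admin = date(2021, 6, 1)
    onset = admin + timedelta(days=4)
    reports: list[ICSReport] = []
    for i in range(n_cases):
        classes = case_classes[i]
        drugs = tuple(
            DrugEntry(f"{cid} vaccine", Role.suspect, cid, admin) for cid in classes
        ) or (DrugEntry(OTHER_DRUG_NAME, Role.suspect, OTHER_CLASS),)
        reports.append(
            ICSReport(
                report_id=f"C{i:0{cw}d}",
                drugs=drugs,
                events=(EventTerm(term_code, term_name, onset),),
                seriousness=frozenset({Seriousness.hospitalization}),
            )
        )
    # non-cases: class k exposes the first b_k non-case reports
    b_list = [(cid, b) for cid, (_a, b) in counts.items()]
    for j in range(n_noncases):
        drugs = tuple(
            DrugEntry(f"{cid} vaccine", Role.suspect, cid, admin)
            for cid, b in b_list
            if j < b
        ) or (DrugEntry(OTHER_DRUG_NAME, Role.suspect, OTHER_CLASS),)
        reports.append(
            ICSReport(
                report_id=f"N{j:0{nw}d}",
                drugs=drugs,
                events=(OTHER_EVENT,),
            )
        )
    return ReportSet(
        reports,
        extraction_date=date(2021, 12, 31),
        metadata={"generator": "pvsignal.simulate.generate_tabulated"},
    )


# ---------------------------------------------------------------------------
# Operating characteristics
# ---------------------------------------------------------------------------


@dataclass
class OperatingCharacteristics:
    """Replicated signal-flagging frequencies for one simulation design."""

    per_class_flag_freq: dict[str, float]
    per_class_eval_freq: dict[str, float]
    type1_error: Optional[float]  # two-sided rejections / evaluable null screens
    flag_rate_null: Optional[float]  # directional flags / evaluable null screens
    power: Optional[float]  # flags / class-replicates, classes with rr > 1
    replicates: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "class_id": list(self.per_class_flag_freq),
                "flag_freq": list(self.per_class_flag_freq.values()),
                "eval_freq": list(self.per_class_eval_freq.values()),
            }
        )


def evaluate_operating_characteristics(
    cfg: SimConfig,
    replicates: int,
    min_exposed_cases: int = 3,
    level: float = 0.95,
    materialize: bool = False,
) -> OperatingCharacteristics:
    """Replicate generate -> screen and aggregate per-class flag frequencies.

    ``type1_error`` is the rate, among *evaluable* null-class screens
    (rr = 1), at which the confidence interval excludes 1 on either side —
    the rejection rate of the level-alpha test, nominally 1 - level.  The
    directional signal flag (lower bound > 1) has nominal null rate
    (1 - level)/2 and is reported as ``flag_rate_null``.  Power counts a
    non-evaluable screen of a true-signal class as a miss.  Per-replicate
    seeds are spawned from the config seed, so results are deterministic
    given (cfg.seed, replicates).
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    _check(cfg)
    cm = make_class_map(cfg)
    null_ids = {c.class_id for c in cfg.classes if c.rr == 1}
    alt_ids = {c.class_id for c in cfg.classes if c.rr != 1}
    flags = {c.class_id: 0 for c in cfg.classes}
    evals = {c.class_id: 0 for c in cfg.classes}
    rejects = {c.class_id: 0 for c in cfg.classes}  # CI excludes 1, either side
    seeds = np.random.SeedSequence(cfg.seed).spawn(replicates)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        if materialize:
            from dataclasses import replace as dc_replace

            sub = dc_replace(cfg, seed=int(ss.generate_state(1)[0] % (2**31)))
            rs = generate_reports(sub)
            st: SignalTable = screen_signals(
                rs, cfg.target_selector, cm, min_exposed_cases, level
            )
        else:
            tables = simulate_tables(cfg, rng)
            st = screen_tables(tables, cm, min_exposed_cases, level)
        for row in st.rows:
            if row.class_id not in flags:
                continue
            if row.included:
                evals[row.class_id] += 1
                if row.signal:
                    flags[row.class_id] += 1
                if row.ci_low > 1.0 or row.ci_high < 1.0:
                    rejects[row.class_id] += 1
    n_eval_null = sum(evals[c] for c in null_ids)
    n_flag_null = sum(flags[c] for c in null_ids)
    n_rej_null = sum(rejects[c] for c in null_ids)
    n_alt = len(alt_ids) * replicates
    n_flag_alt = sum(flags[c] for c in alt_ids)
    return OperatingCharacteristics(
        per_class_flag_freq={c: flags[c] / replicates for c in flags},
        per_class_eval_freq={c: evals[c] / replicates for c in evals},
        type1_error=(n_rej_null / n_eval_null) if n_eval_null else None,
        flag_rate_null=(n_flag_null / n_eval_null) if n_eval_null else None,
        power=(n_flag_alt / n_alt) if n_alt else None,
        replicates=replicates,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# Stock study designs
# ---------------------------------------------------------------------------


def null_config(seed: int = 0) -> SimConfig:
    """Null calibration design: 10 classes, rr = 1 everywhere, with
    prevalence and background rate chosen so expected 2x2 cells are large
    enough (a ~ 20) for the log-normal interval's nominal coverage to be
    meaningful."""
    return SimConfig(
        n_reports=20_000,
        seed=seed,
        background_event_prob=0.01,
        classes=[
            ClassSpec(f"CLS{i:02d}", exposure_prevalence=0.10, rr=1.0)
            for i in range(10)
        ],
    )


def power_config(seed: int = 0, rr: float = 10.0) -> SimConfig:
    """Detection design point: one class at exposure prevalence 0.004
    (an HPV-like database share) with injected rr, background event
    probability 2.4e-4 and two million reports, giving expected exposed-case
    counts around 19 at rr = 10."""
    return SimConfig(
        n_reports=2_000_000,
        seed=seed,
        background_event_prob=2.4e-4,
        classes=[ClassSpec("TARGET", exposure_prevalence=0.004, rr=rr)],
    )
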