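"""Descriptive analysis of a case series: demographics, time to onset,
seriousness, outcome, country, and suspect-drug mention shares.

Conventions:

* medians use the arithmetic midpoint of the two central order statistics
  for even n (so half-integer medians such as 36.5 occur);
* every percentage is computed over the known-value denominator for its
  field (outcomes keep an explicit "unknown" category), and the denominator
  is carried alongside;
* drug-class shares here are *mention-level* (one count per suspect drug
  entry in an exposure class; denominator = all such mentions), in contrast
  to the report-level counting of the contingency tables.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .casenoncase import TermSelector, exposed_classes, is_case
from .icsr import ClassMap, ICSReport, Outcome, ReportSet, Role, Seriousness

logger = logging.getLogger("pvsignal")

__all__ = ["CaseSummary", "time_to_onset", "summarize_cases", "age_by_class",
           "summary_to_json", "render_text_summary"]


def time_to_onset(
    r: ICSReport,
    class_id: str,
    target_term: TermSelector,
    cm: Optional[ClassMap] = None,
) -> Optional[int]:
    """Days from the latest administration of a suspect drug of ``class_id``
    (on or before onset) to the earliest onset of a matching event.

    Returns None when either date is missing; an administration strictly
    after every matching onset is rejected (logged), also returning None.
    """
    onsets = [
        e.onset_date
        for e in r.events
        if e.onset_date is not None and target_term.matches(e.term_code, e.term_name)
    ]
    if not onsets:
        return None
    onset = min(onsets)
    admins = []
    any_admin = False
    for d in r.drugs:
        if d.role is not Role.suspect:
            continue
        cid = d.class_id or (cm.resolve(d.drug_name) if cm else None)
        if cid != class_id or d.administration_date is None:
            continue
        any_admin = True
        if d.administration_date <= onset:
            admins.append(d.administration_date)
    if not admins:
        if any_admin:
            logger.warning(
                "report %s: administration of %s after onset; time to onset dropped",
                r.report_id, class_id,
            )
        return None
    return (onset - max(admins)).days


@dataclass
class CaseSummary:
    """Descriptive statistics of one case series.

    ``denominators`` records, for every percentage, the count it was
    computed over, so each figure can be re-derived.
    """

    n_cases: int
    n_vaccine_cases: int = 0
    pct_vaccine_involved: Optional[float] = None
    pct_female: Optional[float] = None
    median_age: Optional[float] = None
    age_range: Optional[tuple[float, float]] = None
    pct_age_lt15: Optional[float] = None
    pct_age_15_30: Optional[float] = None
    tto_median: Optional[float] = None
    tto_range: Optional[tuple[int, int]] = None
    seriousness_counts: dict[str, int] = field(default_factory=dict)
    outcome_counts: dict[str, dict] = field(default_factory=dict)
    country_shares: dict[str, float] = field(default_factory=dict)
    mention_shares: dict[str, float] = field(default_factory=dict)
    mention_counts: dict[str, int] = field(default_factory=dict)
    denominators: dict[str, int] = field(default_factory=dict)


def _pct(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den else None


def summarize_cases(
    cases: ReportSet,
    all_reports_n: int,
    cm: ClassMap,
    target_term: TermSelector,
) -> CaseSummary:
    """Summarize a case series (all reports must match ``target_term``).

    Age strata are [0, 15) and [15, 30] over known-age cases, with exactly
    15 assigned to the older stratum.  ``n_vaccine_cases`` counts cases with
    at least one suspect drug in an exposure class of the map.
    """
    assert all(is_case(r, target_term) for r in cases), "non-case in case series"
    n = len(cases)
    s = CaseSummary(n_cases=n)
    if n == 0:
        return s

    exposure_ids = set(cm.exposure_class_ids)
    vaccine_cases = [
        r for r in cases if exposed_classes(r, cm) & exposure_ids
    ]
    s.n_vaccine_cases = len(vaccine_cases)
    s.pct_vaccine_involved = _pct(s.n_vaccine_cases, n)
    s.denominators["pct_vaccine_involved"] = n

    from .icsr import Sex

    known_sex = [r for r in cases if r.sex is not Sex.unknown]
    if known_sex:
        s.pct_female = _pct(sum(r.sex is Sex.female for r in known_sex), len(known_sex))
        s.denominators["pct_female"] = len(known_sex)

    ages = sorted(float(r.age_years) for r in cases if r.age_years is not None)
    if ages:
        s.median_age = statistics.median(ages)
        s.age_range = (ages[0], ages[-1])
        s.pct_age_lt15 = _pct(sum(a < 15 for a in ages), len(ages))
        s.pct_age_15_30 = _pct(sum(15 <= a <= 30 for a in ages), len(ages))
        s.denominators["pct_age_lt15"] = len(ages)
        s.denominators["pct_age_15_30"] = len(ages)

    # per-case time to onset: earliest computable lag over exposed classes
    ttos: list[int] = []
    for r in cases:
        lags = [
            lag
            for cid in (exposed_classes(r, cm) & exposure_ids)
            if (lag := time_to_onset(r, cid, target_term, cm)) is not None
        ]
        if lags:
            ttos.append(min(lags))
    if ttos:
        ttos.sort()
        s.tto_median = statistics.median(ttos)
        s.tto_range = (ttos[0], ttos[-1])
        s.denominators["tto_median"] = len(ttos)

    for cat in Seriousness:
        cnt = sum(cat in r.seriousness for r in cases)
        if cnt:
            s.seriousness_counts[cat.value] = cnt

    for oc in Outcome:
        cnt = sum(r.outcome is oc for r in cases)
        s.outcome_counts[oc.value] = {"count": cnt, "pct": _pct(cnt, n)}
    s.denominators["outcome_pct"] = n

    known_country = [r.country for r in cases if r.country]
    if known_country:
        for ctry in sorted(set(known_country)):
            s.country_shares[ctry] = _pct(known_country.count(ctry), len(known_country))
        s.denominators["country_shares"] = len(known_country)

    # mention-level drug-class shares over suspect mentions in exposure classes
    mentions: dict[str, int] = {}
    for r in cases:
        for d in r.drugs:
            if d.role is not Role.suspect:
                continue
            cid = d.class_id or cm.resolve(d.drug_name) or cm.unmapped_class_id
            if cid in exposure_ids:
                mentions[cid] = mentions.get(cid, 0) + 1
    total_mentions = sum(mentions.values())
    s.mention_counts = dict(sorted(mentions.items(), key=lambda kv: (-kv[1], kv[0])))
    if total_mentions:
        s.mention_shares = {
            cid: _pct(cnt, total_mentions) for cid, cnt in s.mention_counts.items()
        }
        s.denominators["mention_shares"] = total_mentions
    return s


def age_by_class(
    cases: ReportSet, cm: ClassMap
) -> dict[str, dict]:
    """Per-class age summary over case reports exposed to the class:
    ``{class_id: {"median": .., "range": (lo, hi), "n": ..}}``; classes with
    no aged exposed cases are absent."""
    out: dict[str, dict] = {}
    for cid in cm.exposure_class_ids:
        ages = sorted(
            float(r.age_years)
            for r in cases
            if r.age_years is not None and cid in exposed_classes(r, cm)
        )
        if ages:
            out[cid] = {
                "median": statistics.median(ages),
                "range": (ages[0], ages[-1]),
                "n": len(ages),
            }
    return out


def summary_to_json(s: CaseSummary, path: Union[str, Path, None] = None) -> str:
    doc = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in s.__dict__.items()
    }
    text = json.dumps(doc, indent=2, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def render_text_summary(s: CaseSummary, cm: Optional[ClassMap] = None) -> str:
    """Human-readable report mirroring a case-series results narrative."""
    L: list[str] = []
    L.append(f"Case series: {s.n_cases} reports")
    if s.pct_vaccine_involved is not None:
        L.append(
            f"  {s.n_vaccine_cases}/{s.n_cases} ({s.pct_vaccine_involved:.1f}%) "
            "involve a suspect drug in an exposure class"
        )
    if s.pct_female is not None:
        L.append(f"  female: {s.pct_female:.1f}% "
                 f"(of {s.denominators.get('pct_female')} with known sex)")
    if s.median_age is not None:
        lo, hi = s.age_range  # type: ignore[misc]
        L.append(f"  median age {s.median_age:g} years (range {lo:g}-{hi:g})")
        L.append(
            f"  aged <15: {s.pct_age_lt15:.1f}%; aged 15-30: {s.pct_age_15_30:.1f}% "
            f"(of {s.denominators.get('pct_age_lt15')} with known age)"
        )
    if s.tto_median is not None:
        lo, hi = s.tto_range  # type: ignore[misc]
        L.append(f"  median time to onset {s.tto_median:g} days (range {lo}-{hi})")
    if s.seriousness_counts:
        parts = "; ".join(f"{k} = {v}" for k, v in s.seriousness_counts.items())
        L.append(f"  seriousness: {parts}")
    if s.outcome_counts:
        parts = "; ".join(
            f"{k}: {v['count']} ({v['pct']:.1f}%)"
            for k, v in s.outcome_counts.items()
            if v["count"]
        )
        L.append(f"  outcomes: {parts}")
    if s.country_shares:
        top = sorted(s.country_shares.items(), key=lambda kv: -kv[1])[:5]
        L.append("  countries: " + "; ".join(f"{c} {p:.1f}%" for c, p in top))
    if s.mention_shares:
        parts = "; ".join(
            f"{(cm.label(c) if cm else c)} {p:.1f}%" for c, p in s.mention_shares.items()
        )
        L.append(f"  suspect-class mention shares (of "
                 f"{s.denominators.get('mention_shares')} mentions): {parts}")
    return "\n".join(L) + "\n"
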