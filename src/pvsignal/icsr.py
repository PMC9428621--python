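"""Domain model for individual case safety reports (ICSRs) and line-listing I/O.

An ICSR is one spontaneous report of suspected adverse drug reaction(s) in one
patient: demographics, the drug(s) with their reported role, the coded event
term(s), seriousness criteria, outcome and reporting country.  A ``ReportSet``
is an extraction of such reports from a reporting database.

The on-disk representation is a flat delimited line listing, one row per
report, with the drug and event lists packed into sub-delimited cells so that
report-level grouping (the counting unit of the case/non-case design) is
preserved in a single file.
"""

from __future__ import annotations

import enum
import io
import logging
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

logger = logging.getLogger("pvsignal")

__all__ = [
    "ConfigurationError",
    "DataError",
    "ParameterError",
    "Role",
    "Sex",
    "Seriousness",
    "Outcome",
    "DrugEntry",
    "EventTerm",
    "ICSReport",
    "ReportSet",
    "ClassMap",
    "FormatConfig",
    "validate_report",
    "read_icsr_table",
    "write_icsr_table",
]


class ConfigurationError(Exception):
    """A configuration (format spec, class map, parameter file) is unusable."""


class DataError(Exception):
    """Input data violate an invariant (duplicate ids, malformed rows)."""


class ParameterError(Exception):
    """An analysis or simulation parameter is out of its admissible range."""


class Role(enum.Enum):
    """Reported role of a drug on an ICSR."""

    suspect = "suspect"
    concomitant = "concomitant"


class Sex(enum.Enum):
    female = "female"
    male = "male"
    unknown = "unknown"


class Seriousness(enum.Enum):
    """Regulatory seriousness criteria; a report may carry several."""

    death = "death"
    life_threatening = "life_threatening"
    hospitalization = "hospitalization"
    disabling = "disabling"
    congenital_anomaly = "congenital_anomaly"
    other_medically_important = "other_medically_important"


class Outcome(enum.Enum):
    recovered = "recovered"
    recovering = "recovering"
    not_recovered_or_sequelae = "not_recovered_or_sequelae"
    fatal = "fatal"
    unknown = "unknown"


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report.

    ``class_id`` is the analysis class (e.g. ``"HPV"``) the coded active
    ingredient resolves to; it may be pre-resolved on the entry or left
    ``None`` for resolution through a :class:`ClassMap` at analysis time.
    """

    drug_name: str
    role: Role
    class_id: Optional[str] = None
    administration_date: Optional[date] = None


@dataclass(frozen=True)
class EventTerm:
    """One coded event term (dictionary lowest-level term) on a report."""

    term_code: str
    term_name: str = ""
    onset_date: Optional[date] = None


@dataclass(frozen=True)
class ICSReport:
    report_id: str
    drugs: tuple[DrugEntry, ...]
    events: tuple[EventTerm, ...]
    age_years: Optional[float] = None
    sex: Sex = Sex.unknown
    country: Optional[str] = None
    seriousness: frozenset[Seriousness] = frozenset()
    outcome: Outcome = Outcome.unknown

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "seriousness", frozenset(self.seriousness))

    @property
    def is_serious(self) -> bool:
        return len(self.seriousness) > 0


def validate_report(r: ICSReport) -> list[str]:
    """Return violation descriptions for ``r``; empty iff well-formed.

    Total: never raises, whatever the field values.
    """
    violations: list[str] = []
    if not isinstance(r.report_id, str) or not r.report_id:
        violations.append("report_id: must be a non-empty string")
    if r.age_years is not None:
        try:
            ok = 0 <= float(r.age_years) <= 120
        except (TypeError, ValueError):
            ok = False
        if not ok:
            violations.append("age_years: must be in [0, 120] when present")
    if not isinstance(r.sex, Sex):
        violations.append("sex: must be a Sex enum value")
    if len(r.drugs) < 1:
        violations.append("drugs: at least one drug entry is required")
    else:
        for i, d in enumerate(r.drugs):
            if not isinstance(d, DrugEntry) or not isinstance(d.role, Role):
                violations.append(f"drugs[{i}]: role must be suspect or concomitant")
    if len(r.events) < 1:
        violations.append("events: at least one event term is required")
    else:
        for i, e in enumerate(r.events):
            if not isinstance(e, EventTerm) or not e.term_code:
                violations.append(f"events[{i}]: term_code must be non-empty")
    if not isinstance(r.outcome, Outcome):
        violations.append("outcome: must be an Outcome enum value")
    for s in r.seriousness:
        if not isinstance(s, Seriousness):
            violations.append("seriousness: entries must be Seriousness enum values")
            break
    return violations


@dataclass
class ReportSet:
    """A collection of ICSRs with unique report ids."""

    reports: list[ICSReport]
    extraction_date: Optional[date] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dups: list[str] = []
        for r in self.reports:
            if r.report_id in seen:
                dups.append(r.report_id)
            seen.add(r.report_id)
        if dups:
            raise DataError(f"duplicate report_id(s): {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        return (
            self.reports == other.reports
            and self.extraction_date == other.extraction_date
        )

    def subset(self, reports: Iterable[ICSReport], **meta) -> "ReportSet":
        md = dict(self.metadata)
        md.update(meta)
        return ReportSet(list(reports), self.extraction_date, md)


# ---------------------------------------------------------------------------
# Drug-name -> class resolution
# ---------------------------------------------------------------------------


@dataclass
class ClassMap:
    """Resolve free-text drug names to analysis class identifiers.

    ``entries`` maps a drug-name pattern to a class id; matching is exact or
    case-insensitive-prefix per ``match_mode``.  Every class id referenced by
    ``entries`` must have a display name in ``labels``.  ``non_exposure``
    lists class ids (e.g. the catch-all for non-vaccine drugs) that never
    count as exposure of interest.
    """

    entries: dict[str, str]
    labels: dict[str, str]
    match_mode: str = "exact"  # "exact" | "iprefix"
    unmapped_class_id: str = "UNMAPPED"
    non_exposure: frozenset[str] = frozenset({"OTHER", "UNMAPPED"})

    def __post_init__(self) -> None:
        if self.match_mode not in ("exact", "iprefix"):
            raise ConfigurationError(
                f"match_mode must be 'exact' or 'iprefix', got {self.match_mode!r}"
            )
        missing = sorted({c for c in self.entries.values() if c not in self.labels})
        if missing:
            raise ConfigurationError(
                f"class ids without a display name: {missing}"
            )
        self.non_exposure = frozenset(self.non_exposure)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.labels

    def resolve(self, drug_name: str) -> Optional[str]:
        if self.match_mode == "exact":
            return self.entries.get(drug_name)
        low = drug_name.lower()
        for pat, cid in self.entries.items():
            if low.startswith(pat.lower()):
                return cid
        return None

    def label(self, class_id: str) -> str:
        return self.labels.get(class_id, class_id)

    @property
    def exposure_class_ids(self) -> list[str]:
        """Class ids that count as exposure of interest, in label order."""
        return [c for c in self.labels if c not in self.non_exposure]

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ClassMap":
        """Load from YAML/JSON: keys entries, labels, optional match_mode etc."""
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"class map file not found: {p}")
        doc = yaml.safe_load(p.read_text())
        if not isinstance(doc, dict) or "labels" not in doc:
            raise ConfigurationError(f"class map {p} must define 'labels'")
        return cls(
            entries=dict(doc.get("entries", {})),
            labels=dict(doc["labels"]),
            match_mode=doc.get("match_mode", "exact"),
            unmapped_class_id=doc.get("unmapped_class_id", "UNMAPPED"),
            non_exposure=frozenset(doc.get("non_exposure", ["OTHER", "UNMAPPED"])),
        )

    def to_file(self, path: Union[str, Path]) -> None:
        doc = {
            "entries": dict(self.entries),
            "labels": dict(self.labels),
            "match_mode": self.match_mode,
            "unmapped_class_id": self.unmapped_class_id,
            "non_exposure": sorted(self.non_exposure),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Line-listing format
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = (
    "report_id",
    "age_years",
    "sex",
    "country",
    "drugs",
    "events",
    "seriousness",
    "outcome",
)


@dataclass
class FormatConfig:
    """Dialect of the delimited line listing.

    Drugs are packed as ``name|role|class|admin_date`` items joined by
    ``list_sep``; events as ``code|name|onset_date``; seriousness as a
    ``list_sep``-joined list of category names.  Dates are ISO-8601.
    """

    delimiter: str = ","
    list_sep: str = ";"
    field_sep: str = "|"
    columns: dict[str, str] = field(
        default_factory=lambda: {c: c for c in _MANDATORY_COLUMNS}
    )

    def __post_init__(self) -> None:
        missing = [c for c in _MANDATORY_COLUMNS if c not in self.columns]
        if missing:
            raise ConfigurationError(f"format_config missing column roles: {missing}")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "FormatConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            delimiter=doc.get("delimiter", ","),
            list_sep=doc.get("list_sep", ";"),
            field_sep=doc.get("field_sep", "|"),
            columns={**{c: c for c in _MANDATORY_COLUMNS}, **doc.get("columns", {})},
        )


def _fmt_date(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def _parse_date(s: str, where: str) -> Optional[date]:
    if not s:
        return None
    try:
        return date.fromisoformat(s)
    except ValueError as exc:
        raise DataError(f"{where}: invalid ISO-8601 date {s!r}") from exc


def _pack_drugs(drugs: Sequence[DrugEntry], fmt: FormatConfig) -> str:
    items = []
    for d in drugs:
        parts = (d.drug_name, d.role.value, d.class_id or "", _fmt_date(d.administration_date))
        for p in parts:
            if fmt.list_sep in p or fmt.field_sep in p or fmt.delimiter in p:
                raise DataError(
                    f"drug field {p!r} contains a reserved delimiter"
                )
        items.append(fmt.field_sep.join(parts))
    return fmt.list_sep.join(items)


def _unpack_drugs(cell: str, fmt: FormatConfig, where: str) -> tuple[DrugEntry, ...]:
    if not cell:
        return ()
    out = []
    for item in cell.split(fmt.list_sep):
        parts = item.split(fmt.field_sep)
        if len(parts) != 4:
            raise DataError(f"{where}: malformed drug item {item!r}")
        name, role, cid, admin = parts
        try:
            role_e = Role(role)
        except ValueError as exc:
            raise DataError(f"{where}: unknown drug role {role!r}") from exc
        out.append(
            DrugEntry(name, role_e, cid or None, _parse_date(admin, where))
        )
    return tuple(out)


def _pack_events(events: Sequence[EventTerm], fmt: FormatConfig) -> str:
    items = []
    for e in events:
        parts = (e.term_code, e.term_name, _fmt_date(e.onset_date))
        for p in parts:
            if fmt.list_sep in p or fmt.field_sep in p or fmt.delimiter in p:
                raise DataError(f"event field {p!r} contains a reserved delimiter")
        items.append(fmt.field_sep.join(parts))
    return fmt.list_sep.join(items)


def _unpack_events(cell: str, fmt: FormatConfig, where: str) -> tuple[EventTerm, ...]:
    if not cell:
        return ()
    out = []
    for item in cell.split(fmt.list_sep):
        parts = item.split(fmt.field_sep)
        if len(parts) != 3:
            raise DataError(f"{where}: malformed event item {item!r}")
        code, name, onset = parts
        out.append(EventTerm(code, name, _parse_date(onset, where)))
    return tuple(out)


def write_icsr_table(
    rs: ReportSet,
    sink: Union[str, Path, io.TextIOBase],
    format_config: Optional[FormatConfig] = None,
) -> None:
    """Serialize ``rs`` to a delimited line listing re-readable by
    :func:`read_icsr_table` with the same format config."""
    fmt = format_config or FormatConfig()
    cols = fmt.columns
    rows = []
    for r in rs:
        rows.append(
            {
                cols["report_id"]: r.report_id,
                cols["age_years"]: "" if r.age_years is None else repr(float(r.age_years)),
                cols["sex"]: r.sex.value,
                cols["country"]: r.country or "",
                cols["drugs"]: _pack_drugs(r.drugs, fmt),
                cols["events"]: _pack_events(r.events, fmt),
                cols["seriousness"]: fmt.list_sep.join(
                    sorted(s.value for s in r.seriousness)
                ),
                cols["outcome"]: r.outcome.value,
            }
        )
    df = pd.DataFrame(rows, columns=[cols[c] for c in _MANDATORY_COLUMNS])
    df.to_csv(sink, sep=fmt.delimiter, index=False)


def read_icsr_table(
    source: Union[str, Path, io.TextIOBase],
    format_config: Optional[FormatConfig] = None,
    extraction_date: Optional[date] = None,
) -> ReportSet:
    """Parse a delimited line listing into a validated :class:`ReportSet`.

    Rows that fail report validation are rejected; their diagnostics are
    logged and recorded under ``metadata['rejected_rows']``.  A missing
    mandatory column raises :class:`ConfigurationError`; duplicated report
    ids raise :class:`DataError` listing the duplicates.
    """
    fmt = format_config or FormatConfig()
    cols = fmt.columns
    df = pd.read_csv(source, sep=fmt.delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if cols[c] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"missing mandatory column(s): {[cols[c] for c in missing]}"
        )

    reports: list[ICSReport] = []
    rejected: list[dict] = []
    for idx, row in df.iterrows():
        where = f"row {idx + 2}"  # 1-based, after header
        try:
            rid = row[cols["report_id"]]
            age_s = row[cols["age_years"]]
            sex_s = row[cols["sex"]] or "unknown"
            try:
                sex = Sex(sex_s)
            except ValueError as exc:
                raise DataError(f"{where}: unknown sex {sex_s!r}") from exc
            try:
                outcome = Outcome(row[cols["outcome"]] or "unknown")
            except ValueError as exc:
                raise DataError(
                    f"{where}: unknown outcome {row[cols['outcome']]!r}"
                ) from exc
            ser_cell = row[cols["seriousness"]]
            try:
                seriousness = frozenset(
                    Seriousness(s) for s in ser_cell.split(fmt.list_sep) if s
                )
            except ValueError as exc:
                raise DataError(
                    f"{where}: unknown seriousness category in {ser_cell!r}"
                ) from exc
            report = ICSReport(
                report_id=rid,
                age_years=float(age_s) if age_s else None,
                sex=sex,
                country=row[cols["country"]] or None,
                drugs=_unpack_drugs(row[cols["drugs"]], fmt, where),
                events=_unpack_events(row[cols["events"]], fmt, where),
                seriousness=seriousness,
                outcome=outcome,
            )
        except DataError as exc:
            rejected.append({"row": idx + 2, "error": str(exc)})
            logger.warning("rejected %s: %s", where, exc)
            continue
        violations = validate_report(report)
        if violations:
            rejected.append({"row": idx + 2, "error": "; ".join(violations)})
            logger.warning("rejected %s: %s", where, "; ".join(violations))
            continue
        reports.append(report)

    ids = [r.report_id for r in reports]
    dup = sorted({i for i in ids if ids.count(i) > 1}) if len(set(ids)) != len(ids) else []
    if dup:
        raise DataError(f"duplicate report_id(s): {dup}")
    md: dict = {}
    if rejected:
        md["rejected_rows"] = rejected
    return ReportSet(reports, extraction_date=extraction_date, metadata=md)
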