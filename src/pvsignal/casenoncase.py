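"""Case/non-case partition and per-class 2x2 contingency tables.

In the case/non-case design, reports coded with the event term of interest
are the cases and every other report in the database is a non-case.  For a
drug class X the report-level 2x2 table is

    a = cases exposed to X          b = non-cases exposed to X
    c = cases not exposed to X      d = non-cases not exposed to X

The comparator (c, d) is *all* other reports, irrespective of what drugs
they carry: c includes cases exposed only to other classes.  Exposure means
carrying at least one suspect-role drug of the class; a report contributes
at most one count to any class, however many matching drug mentions it has.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .icsr import ClassMap, ConfigurationError, ICSReport, ReportSet, Role

__all__ = [
    "TermSelector",
    "TwoByTwoTable",
    "is_case",
    "exposed_classes",
    "partition_cases",
    "build_contingency",
    "build_all_contingencies",
]


@dataclass(frozen=True)
class TermSelector:
    """Select reports by event term: exact code match, or exact name match
    (case-insensitive by default).  At least one of code/name is required."""

    term_code: Optional[str] = None
    term_name: Optional[str] = None
    name_case_insensitive: bool = True

    def __post_init__(self) -> None:
        if self.term_code is None and self.term_name is None:
            raise ConfigurationError("TermSelector needs a term_code or a term_name")

    def matches(self, term_code: str, term_name: str) -> bool:
        if self.term_code is not None and term_code == self.term_code:
            return True
        if self.term_name is not None:
            if self.name_case_insensitive:
                return term_name.lower() == self.term_name.lower()
            return term_name == self.term_name
        return False

    @property
    def key(self) -> str:
        return self.term_code if self.term_code is not None else self.term_name  # type: ignore[return-value]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Report counts for one (drug class, event term) pair."""

    a: int  # exposed cases
    b: int  # exposed non-cases
    c: int  # unexposed cases
    d: int  # unexposed non-cases
    class_id: str = ""
    term_code: str = ""

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def is_case(r: ICSReport, target_term: TermSelector) -> bool:
    """True iff any event term on ``r`` matches the selector."""
    return any(target_term.matches(e.term_code, e.term_name) for e in r.events)


def exposed_classes(
    r: ICSReport,
    cm: ClassMap,
    roles: frozenset[Role] = frozenset({Role.suspect}),
) -> set[str]:
    """Distinct class ids of ``r``'s drugs whose role is in ``roles``.

    A drug with no pre-resolved class and no class-map match is recorded
    under the map's configured unmapped class id, never silently dropped.
    Two suspect drugs of the same class contribute the class once.
    """
    out: set[str] = set()
    for d in r.drugs:
        if d.role not in roles:
            continue
        cid = d.class_id or cm.resolve(d.drug_name) or cm.unmapped_class_id
        out.add(cid)
    return out


def partition_cases(
    rs: ReportSet, target_term: TermSelector
) -> tuple[ReportSet, ReportSet]:
    """Disjoint, exhaustive split of ``rs`` into (cases, non_cases)."""
    cases, non_cases = [], []
    for r in rs:
        (cases if is_case(r, target_term) else non_cases).append(r)
    return (
        rs.subset(cases, selection="cases", term=target_term.key),
        rs.subset(non_cases, selection="non_cases", term=target_term.key),
    )


def build_contingency(
    rs: ReportSet,
    target_term: TermSelector,
    class_id: str,
    cm: ClassMap,
    roles: frozenset[Role] = frozenset({Role.suspect}),
) -> TwoByTwoTable:
    """Tally the report-level 2x2 table for one class against all other
    reports."""
    if class_id not in cm:
        raise ConfigurationError(f"unknown class_id {class_id!r}")
    a = b = c = d = 0
    for r in rs:
        case = is_case(r, target_term)
        exposed = class_id in exposed_classes(r, cm, roles)
        if case and exposed:
            a += 1
        elif not case and exposed:
            b += 1
        elif case:
            c += 1
        else:
            d += 1
    return TwoByTwoTable(a, b, c, d, class_id=class_id, term_code=target_term.key)


def build_all_contingencies(
    rs: ReportSet,
    target_term: TermSelector,
    cm: ClassMap,
    class_ids: Optional[Iterable[str]] = None,
    roles: frozenset[Role] = frozenset({Role.suspect}),
) -> dict[str, TwoByTwoTable]:
    """One 2x2 table per class (default: every exposure class in the map),
    in a single pass over the reports."""
    ids = list(class_ids) if class_ids is not None else cm.exposure_class_ids
    for cid in ids:
        if cid not in cm:
            raise ConfigurationError(f"unknown class_id {cid!r}")
    n_cases = 0
    n_total = 0
    a: dict[str, int] = {cid: 0 for cid in ids}
    b: dict[str, int] = {cid: 0 for cid in ids}
    for r in rs:
        n_total += 1
        case = is_case(r, target_term)
        if case:
            n_cases += 1
        exp = exposed_classes(r, cm, roles)
        for cid in exp:
            if cid not in a:
                continue
            if case:
                a[cid] += 1
            else:
                b[cid] += 1
    return {
        cid: TwoByTwoTable(
            a[cid],
            b[cid],
            n_cases - a[cid],
            n_total - n_cases - b[cid],
            class_id=cid,
            term_code=target_term.key,
        )
        for cid in ids
    }
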