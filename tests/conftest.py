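from datetime import date

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, print_blob=True)
settings.load_profile("deterministic")

from pvsignal import (
    ClassMap,
    DrugEntry,
    EventTerm,
    ICSReport,
    Outcome,
    ReportSet,
    Role,
    Seriousness,
    Sex,
    TermSelector,
)

TARGET = TermSelector(term_code="LLT0001", term_name="Anti-NMDA receptor encephalitis")


@pytest.fixture
def target():
    return TARGET


@pytest.fixture
def class_map():
    return ClassMap(
        entries={
            "HPV vaccine": "HPV",
            "influenza vaccine": "INFLUENZA",
            "other medicinal product": "OTHER",
        },
        labels={
            "HPV": "HPV vaccine",
            "INFLUENZA": "Influenza vaccine",
            "OTHER": "Other drugs",
        },
    )


def make_report(
    rid,
    classes=(),
    case=False,
    roles=None,
    age=None,
    sex=Sex.unknown,
    country=None,
    admin=None,
    onset=None,
    outcome=Outcome.unknown,
    serious=(),
):
    """Small-report factory: one suspect drug per class (or a placeholder),
    and the target event term iff ``case``."""
    roles = roles or [Role.suspect] * len(classes)
    drugs = tuple(
        DrugEntry(f"{c} vaccine", r, c, admin) for c, r in zip(classes, roles)
    ) or (DrugEntry("other medicinal product", Role.suspect, "OTHER"),)
    if case:
        events = (EventTerm("LLT0001", "Anti-NMDA receptor encephalitis", onset),)
    else:
        events = (EventTerm("EVT_OTHER", "Other reaction", onset),)
    return ICSReport(
        report_id=rid,
        drugs=drugs,
        events=events,
        age_years=age,
        sex=sex,
        country=country,
        outcome=outcome,
        seriousness=frozenset(serious),
    )


@pytest.fixture
def toy_reports(class_map):
    """4 reports: one per 2x2 cell of the HPV table."""
    return ReportSet(
        [
            make_report("r1", ("HPV",), case=True),
            make_report("r2", (), case=True),
            make_report("r3", ("HPV",), case=False),
            make_report("r4", (), case=False),
        ],
        extraction_date=date(2021, 12, 31),
    )
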