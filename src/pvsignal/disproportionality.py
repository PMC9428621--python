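"""Reporting odds ratio, Woolf confidence interval, Pearson chi-square, and
multi-class signal screening.

The reporting odds ratio (ROR) for a 2x2 report-count table (a, b, c, d) is
ad/bc.  Its confidence interval is the log-normal (Woolf) interval

    exp( ln ROR  +/-  z * sqrt(1/a + 1/b + 1/c + 1/d) )

and the p-value is the upper tail of chi-square(1 df) at the Pearson
statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)), without continuity
correction.  A class is a signal when its lower CI bound exceeds 1
(equivalently, a two-sided Wald test on ln ROR rejects at the same level);
classes with fewer exposed cases than the minimum-count filter are not
evaluated.  ROR measures reporting disproportionality, not causal risk.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from scipy import stats

from .casenoncase import TermSelector, TwoByTwoTable, build_all_contingencies
from .icsr import ClassMap, ParameterError, ReportSet, Role

__all__ = [
    "ZeroCellError",
    "SignalStatus",
    "SignalRow",
    "SignalTable",
    "ror",
    "woolf_ci",
    "pearson_chi2_p",
    "screen_tables",
    "screen_signals",
    "classify_signal",
    "signal_table_to_frame",
    "write_signal_table",
]


class ZeroCellError(ParameterError):
    """A statistic is undefined because a required cell or margin is zero."""


class SignalStatus(enum.Enum):
    signal = "signal"
    no_signal = "no_signal"
    not_evaluable = "not_evaluable"


def _corrected(t: TwoByTwoTable, zero_correction: bool) -> tuple[float, float, float, float]:
    """Apply the Haldane-Anscombe +0.5 correction when requested and a zero
    cell is present; otherwise return the cells unchanged."""
    cells = t.cells()
    if zero_correction and 0 in cells:
        return tuple(x + 0.5 for x in cells)  # type: ignore[return-value]
    return tuple(float(x) for x in cells)  # type: ignore[return-value]


def ror(t: TwoByTwoTable, zero_correction: bool = False) -> float:
    """Reporting odds ratio ad/bc."""
    a, b, c, d = _corrected(t, zero_correction)
    if b == 0 or c == 0:
        zero = "b" if b == 0 else "c"
        raise ZeroCellError(f"ROR undefined: cell {zero} is zero (class {t.class_id!r})")
    return (a * d) / (b * c)


def woolf_ci(
    t: TwoByTwoTable, level: float = 0.95, zero_correction: bool = False
) -> tuple[float, float]:
    """Log-normal (Woolf) confidence interval for the ROR at ``level``."""
    if not 0 < level < 1:
        raise ParameterError(f"confidence level must be in (0, 1), got {level}")
    a, b, c, d = _corrected(t, zero_correction)
    if min(a, b, c, d) == 0:
        zero = "abcd"[(a, b, c, d).index(0.0)]
        raise ZeroCellError(
            f"Woolf CI undefined: cell {zero} is zero (class {t.class_id!r})"
        )
    point = (a * d) / (b * c)
    s = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return (math.exp(math.log(point) - z * s), math.exp(math.log(point) + z * s))


def pearson_chi2_p(t: TwoByTwoTable) -> float:
    """Upper-tail chi-square(1) probability of the Pearson statistic, no
    continuity correction."""
    a, b, c, d = (float(x) for x in t.cells())
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ZeroCellError(
            f"chi-square undefined: zero margin (class {t.class_id!r})"
        )
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class SignalRow:
    """Screening result for one drug class."""

    class_id: str
    display_name: str
    table: TwoByTwoTable
    included: bool
    ror: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None

    @property
    def signal(self) -> bool:
        return self.included and self.ci_low is not None and self.ci_low > 1.0


def classify_signal(row: SignalRow) -> SignalStatus:
    if not row.included:
        return SignalStatus.not_evaluable
    return SignalStatus.signal if row.signal else SignalStatus.no_signal


@dataclass
class SignalTable:
    """All screened classes for one event term, included rows first in
    descending ROR order, excluded rows last."""

    rows: list[SignalRow]
    term_code: str
    n_reports: int
    n_cases: int
    level: float = 0.95
    min_exposed_cases: int = 3
    metadata: dict = field(default_factory=dict)

    @property
    def included_rows(self) -> list[SignalRow]:
        return [r for r in self.rows if r.included]

    @property
    def signals(self) -> list[SignalRow]:
        return [r for r in self.rows if r.signal]


def _make_row(
    cid: str, cm: ClassMap, t: TwoByTwoTable, min_exposed_cases: int, level: float,
    zero_correction: bool,
) -> SignalRow:
    included = t.a >= min_exposed_cases
    if not included:
        return SignalRow(cid, cm.label(cid), t, included=False)
    r = ror(t, zero_correction)
    lo, hi = woolf_ci(t, level, zero_correction)
    p = pearson_chi2_p(t)
    return SignalRow(cid, cm.label(cid), t, True, r, lo, hi, p)


def screen_tables(
    tables: dict[str, TwoByTwoTable],
    cm: ClassMap,
    min_exposed_cases: int = 3,
    level: float = 0.95,
    zero_correction: bool = False,
    term_code: str = "",
) -> SignalTable:
    """Screen pre-tallied 2x2 tables (e.g. from the counts-only virtual path
    of the generator)."""
    if min_exposed_cases < 1:
        raise ParameterError("min_exposed_cases must be >= 1")
    rows = [
        _make_row(cid, cm, t, min_exposed_cases, level, zero_correction)
        for cid, t in tables.items()
    ]
    rows.sort(
        key=lambda r: (
            not r.included,
            -(r.ror if r.ror is not None else 0.0),
            -r.table.a,
            r.class_id,
        )
    )
    any_t = next(iter(tables.values()), None)
    return SignalTable(
        rows=rows,
        term_code=term_code or (any_t.term_code if any_t else ""),
        n_reports=any_t.n_total if any_t else 0,
        n_cases=any_t.n_cases if any_t else 0,
        level=level,
        min_exposed_cases=min_exposed_cases,
        metadata={"multiple_testing_correction": "none"},
    )


def screen_signals(
    rs: ReportSet,
    target_term: TermSelector,
    cm: ClassMap,
    min_exposed_cases: int = 3,
    level: float = 0.95,
    zero_correction: bool = False,
    roles: frozenset[Role] = frozenset({Role.suspect}),
) -> SignalTable:
    """Full screen: tally one 2x2 table per exposure class of the map over
    ``rs``, apply the minimum-count filter, compute ROR/CI/p for included
    rows and flag signals (lower CI bound > 1)."""
    tables = build_all_contingencies(rs, target_term, cm, roles=roles)
    st = screen_tables(
        tables, cm, min_exposed_cases, level, zero_correction, term_code=target_term.key
    )
    st.n_reports = len(rs)
    if tables:
        st.n_cases = next(iter(tables.values())).n_cases
    else:
        from .casenoncase import partition_cases

        cases, _ = partition_cases(rs, target_term)
        st.n_cases = len(cases)
    return st


# ---------------------------------------------------------------------------
# Display rounding and export
# ---------------------------------------------------------------------------


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (half away from zero)."""
    if x == 0:
        return 0.0
    from decimal import Decimal, ROUND_HALF_UP

    exp = math.floor(math.log10(abs(x)))
    q = Decimal(10) ** (exp - sig + 1)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(x: float, ndigits: int) -> float:
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: Optional[float]) -> str:
    if p is None:
        return ""
    return "<0.001" if p < 0.0005 else f"{p:.3f}"


def signal_table_to_frame(st: SignalTable, rounded: bool = False) -> pd.DataFrame:
    """Tabular view: full precision, or display-rounded (ROR 2 d.p., CI
    bounds 3 s.f., p to 3 decimals with '<0.001' below 0.0005)."""
    recs = []
    for r in st.rows:
        rec = {
            "class_id": r.class_id,
            "display_name": r.display_name,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "included": r.included,
            "signal": r.signal,
        }
        if rounded:
            rec["ror"] = None if r.ror is None else round_half_up(r.ror, 2)
            rec["ci_low"] = None if r.ci_low is None else round_sig(r.ci_low, 3)
            rec["ci_high"] = None if r.ci_high is None else round_sig(r.ci_high, 3)
            rec["p_value"] = format_p(r.p_value)
        else:
            rec["ror"] = r.ror
            rec["ci_low"] = r.ci_low
            rec["ci_high"] = r.ci_high
            rec["p_value"] = r.p_value
        recs.append(rec)
    cols = [
        "class_id", "display_name", "a", "b", "c", "d",
        "ror", "ci_low", "ci_high", "p_value", "included", "signal",
    ]
    return pd.DataFrame(recs, columns=cols)


def write_signal_table(
    st: SignalTable,
    path: Union[str, Path],
    fmt: str = "csv",
    rounded: bool = False,
) -> None:
    """Write the screen as delimited text or JSON."""
    df = signal_table_to_frame(st, rounded=rounded)
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        doc = {
            "term_code": st.term_code,
            "n_reports": st.n_reports,
            "n_cases": st.n_cases,
            "level": st.level,
            "min_exposed_cases": st.min_exposed_cases,
            "metadata": st.metadata,
            "rows": json.loads(df.to_json(orient="records")),
        }
        path.write_text(json.dumps(doc, indent=2))
    else:
        raise ParameterError(f"unknown signal-table format {fmt!r}")
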