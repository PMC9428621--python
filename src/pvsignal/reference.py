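"""Published VigiBase screen of anti-NMDA receptor encephalitis vs vaccines.

Printed report counts from a published case/non-case disproportionality
screen of the MedDRA lower-level term "Anti-NMDA receptor encephalitis"
against vaccine classes in the WHO global ICSR database (extraction up to
2021-12-31): per-class exposed-case (a) and exposed-non-case (b) counts for
the eight classes with at least three exposed cases, plus the database
totals.  These counts are the *inputs* a re-analysis starts from; the raw
line listing itself is access-restricted.

Classes reported with fewer than three exposed cases (rabies, typhoid,
hepatitis A/B combinations) had their exact cell counts unpublished; the
entries in ``EXCLUDED_SCREEN_COUNTS`` are synthetic stand-ins consistent
with the published totals (43 exposed cases over included classes, 51
suspect-vaccine mentions, 29 vaccine-involved cases) and are used only to
exercise the minimum-count filter.
"""

from __future__ import annotations

from .icsr import ClassMap

N_REPORTS = 29_758_737  # total reports in the database at extraction
N_CASES = 70  # reports coded with the target term
N_VACCINE_CASES = 29  # cases with at least one suspect vaccine
TARGET_TERM_CODE = "LLT0001"  # synthetic stand-in code; matching is by name
TARGET_TERM_NAME = "Anti-NMDA receptor encephalitis"

# class_id -> (a, b): published counts for the eight evaluable classes
SCREEN_COUNTS: dict[str, tuple[int, int]] = {
    "HPV": (8, 116_283),
    "DTP_POLIO": (8, 70_006),
    "INFLUENZA": (7, 280_525),
    "VARICELLA_ZOSTER": (5, 193_141),
    "PNEUMOCOCCAL": (4, 241_627),
    "HIB": (4, 89_544),
    "COVID19": (4, 2_881_218),
    "YELLOW_FEVER": (3, 26_614),
}

# synthetic (a, b) stand-ins for the classes excluded by the a >= 3 filter;
# a-counts sum with the published ones to the 51 printed mentions
EXCLUDED_SCREEN_COUNTS: dict[str, tuple[int, int]] = {
    "RABIES": (2, 7_966),
    "TYPHOID": (2, 12_028),
    "HEP_AB": (2, 29_900),
    "HEP_A": (1, 18_410),
    "HEP_B": (1, 52_551),
}

CLASS_LABELS: dict[str, str] = {
    "HPV": "HPV vaccine",
    "DTP_POLIO": "DTP-polio vaccine",
    "INFLUENZA": "Influenza vaccine",
    "VARICELLA_ZOSTER": "Varicella zoster vaccine",
    "PNEUMOCOCCAL": "Pneumococcal vaccine",
    "HIB": "HIB vaccine",
    "COVID19": "COVID-19 vaccine",
    "YELLOW_FEVER": "Yellow fever vaccine",
    "RABIES": "Rabies vaccine",
    "TYPHOID": "Typhoid vaccine",
    "HEP_AB": "Hepatitis A/B vaccine",
    "HEP_A": "Hepatitis A vaccine",
    "HEP_B": "Hepatitis B vaccine",
    "OTHER": "Other drugs",
}


def full_screen_counts() -> dict[str, tuple[int, int]]:
    """Published counts plus the synthetic below-filter classes."""
    out = dict(SCREEN_COUNTS)
    out.update(EXCLUDED_SCREEN_COUNTS)
    return out


def reference_class_map() -> ClassMap:
    """Class map for the vaccine-class screen."""
    entries = {label: cid for cid, label in CLASS_LABELS.items() if cid != "OTHER"}
    entries.update({f"{cid} vaccine": cid for cid in CLASS_LABELS if cid != "OTHER"})
    entries["other medicinal product"] = "OTHER"
    return ClassMap(entries=entries, labels=dict(CLASS_LABELS))


def scaled_screen_counts(factor: int = 1000) -> tuple[dict[str, tuple[int, int]], int, int]:
    """Counts with b-cells and the report total divided by ``factor``
    (rounded), a-cells and the case total kept, for fast materialized runs.

    Returns (counts, n_cases, n_reports).
    """
    counts = {
        cid: (a, round(b / factor)) for cid, (a, b) in full_screen_counts().items()
    }
    return counts, N_CASES, round(N_REPORTS / factor)
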