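"""Case/control classification from ICD-10 underlying cause of death.

Cases are firearm suicide decedents (underlying cause X72--X74, any
subdivision).  Controls are decedents from unintentional motor-vehicle
crashes as an occupant or driver, defined by an explicit closed list of
ICD-10 transport-accident code ranges.  Intentional and undetermined-intent
transport deaths are excluded structurally: their codes (X82, Y03, Y32)
simply do not appear in the control list, so no separate intent filter is
required.

Eligibility mirrors a legal-handgun-purchaser cohort: decedents under the
legal purchase age of 21 are removed first, then records missing sex, then
records missing county urbanicity.  The order is fixed so that exclusion
reports reconcile exactly and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CauseClassification",
    "EligibilityReport",
    "classify_manner",
    "classify_persons",
    "apply_eligibility",
    "CASE_ROOTS",
    "CONTROL_PREFIXES",
]

# Firearm suicide: X72 (handgun), X73 (rifle/shotgun/larger), X74 (other and
# unspecified firearm).  Matching is on the 3-character root, so any
# subdivision (e.g. X72.0) is a case.
CASE_ROOTS = frozenset({"X72", "X73", "X74"})

# Motor-vehicle crash occupant/driver control definition.  Entries are either
# a 3-character range (matches any code whose 3-character root falls
# lexicographically inside, plus all subdivisions) or a 4-character range
# (matches only the listed 4-character codes and their further subdivisions).
_CONTROL_RANGES_3 = [
    ("V02", "V04"),
    ("V12", "V14"),
    ("V20", "V79"),
    ("V83", "V86"),
]
_CONTROL_RANGES_4 = [
    ("V090", "V090"),
    ("V092", "V092"),
    ("V190", "V192"),
    ("V194", "V196"),
    ("V803", "V805"),
    ("V810", "V811"),
    ("V820", "V821"),
    ("V870", "V878"),
    ("V880", "V888"),
    ("V890", "V890"),
    ("V892", "V892"),
]


def _expand_4char(lo: str, hi: str) -> list[str]:
    root, lo_d, hi_d = lo[:3], int(lo[3]), int(hi[3])
    return [f"{root}{d}" for d in range(lo_d, hi_d + 1)]


#: All 4-character control prefixes, fully expanded.
CONTROL_PREFIXES = frozenset(
    p for lo, hi in _CONTROL_RANGES_4 for p in _expand_4char(lo, hi)
)


@dataclass(frozen=True)
class CauseClassification:
    """Outcome of the case/control membership test for one ICD-10 code."""

    status: str  # "case" | "control" | "ineligible"
    matched_rule: str | None = None


@dataclass
class EligibilityReport:
    """Bookkeeping for the eligibility filters, with exact reconciliation.

    Each excluded person is counted once, at the first filter that removes
    them (age, then missing sex, then missing urbanicity), so
    ``n_input == n_excluded_age + n_excluded_missing + n_retained`` always.
    """

    n_input: int = 0
    n_excluded_age: int = 0
    n_excluded_missing: int = 0
    n_retained: int = 0
    exclusions: dict = field(default_factory=dict)  # person_id -> reason

    def reconciles(self) -> bool:
        return (
            self.n_input
            == self.n_excluded_age + self.n_excluded_missing + self.n_retained
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_age": self.n_excluded_age,
            "n_excluded_missing": self.n_excluded_missing,
            "n_retained": self.n_retained,
            "exclusions": dict(self.exclusions),
        }


def normalize_icd10(code: str) -> str:
    """Uppercase, strip whitespace and the optional decimal point."""
    if code is None:
        return ""
    return str(code).strip().upper().replace(".", "")


def classify_manner(underlying_cause_icd10: str) -> CauseClassification:
    """Classify an ICD-10 underlying cause of death as case/control/ineligible.

    Pure function; never raises.  Garbled or empty codes are ineligible with
    ``matched_rule=None``.  Both dotted ("V19.0") and undotted ("V190")
    spellings are accepted.
    """
    code = normalize_icd10(underlying_cause_icd10)
    if len(code) < 3:
        return CauseClassification("ineligible", None)
    root = code[:3]
    if root in CASE_ROOTS:
        return CauseClassification("case", f"X72-X74:{root}")
    if root[0] != "V":
        return CauseClassification("ineligible", None)
    for lo, hi in _CONTROL_RANGES_3:
        if lo <= root <= hi:
            return CauseClassification("control", f"{lo}-{hi}")
    if len(code) >= 4 and code[:4] in CONTROL_PREFIXES:
        return CauseClassification("control", code[:4])
    return CauseClassification("ineligible", None)


def _assert_disjoint() -> None:
    # case roots are X-codes, control rules are V-codes: structurally disjoint,
    # asserted here once at import.
    assert not CASE_ROOTS & {p[:3] for p in CONTROL_PREFIXES}
    assert all(lo[0] == "V" and hi[0] == "V" for lo, hi in _CONTROL_RANGES_3)


_assert_disjoint()


def classify_persons(persons: pd.DataFrame) -> pd.DataFrame:
    """Add ``status`` and ``matched_rule`` columns from the cause-of-death code.

    Parameters
    ----------
    persons : DataFrame with an ``underlying_cause_icd10`` column.
    """
    cls = persons["underlying_cause_icd10"].map(classify_manner)
    out = persons.copy()
    out["status"] = [c.status for c in cls]
    out["matched_rule"] = [c.matched_rule for c in cls]
    return out


def apply_eligibility(
    persons: pd.DataFrame, min_age: float = 21.0
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Apply the cohort eligibility filters in a fixed order.

    Removes, in order: age < ``min_age`` (the legal handgun purchase age);
    missing sex; missing county urbanicity.  Returns the retained rows and a
    report whose counts reconcile exactly.  Boundary: age exactly
    ``min_age`` is retained.
    """
    report = EligibilityReport(n_input=len(persons))
    if persons.empty:
        return persons.copy(), report

    def _is_missing(s: pd.Series) -> pd.Series:
        return s.isna() | s.astype(str).str.strip().str.lower().isin(
            {"", "missing", "nan"}
        )

    age_bad = persons["age_years"] < min_age
    sex_bad = _is_missing(persons["sex"]) & ~age_bad
    urb_bad = _is_missing(persons["urbanicity"]) & ~age_bad & ~sex_bad

    for pid in persons.loc[age_bad, "person_id"]:
        report.exclusions[pid] = "age"
    for pid in persons.loc[sex_bad, "person_id"]:
        report.exclusions[pid] = "missing_sex"
    for pid in persons.loc[urb_bad, "person_id"]:
        report.exclusions[pid] = "missing_urbanicity"

    keep = ~(age_bad | sex_bad | urb_bad)
    report.n_excluded_age = int(age_bad.sum())
    report.n_excluded_missing = int(sex_bad.sum() + urb_bad.sum())
    report.n_retained = int(keep.sum())
    return persons.loc[keep].copy(), report
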