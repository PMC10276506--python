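"""Person-level exposure phenotyping from visit-level ICD-9-CM codes.

Hospital/ED discharge diagnoses and external-cause-of-injury codes (pooled,
"any diagnostic field") are mapped to six clinical exposure categories --
mental illness, substance use, pain, chronic disease, assault, and suicidal
ideation/attempt -- and their disaggregated components, over a lookback
window ending at the death (index) date.

Matching is by ICD-9-CM code prefix, anchored at the start of the code,
after stripping the decimal point; both dotted ("296.2") and undotted
("2962") dialects therefore behave identically.  The window is a closed
calendar interval ``[death - lookback, death]``, computed with calendar
arithmetic rather than a fixed day count.

The intent restriction on drug poisonings (unintentional only) lives inside
the code map itself: poisoning components list only unintentional
external-cause prefixes, so no runtime intent flag exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "TAXONOMY",
    "CATEGORIES",
    "CodeMap",
    "load_code_map",
    "default_code_map",
    "code_exposures",
    "summarize_table_one",
]

#: Category -> tuple of component labels.  Assault has no components and is
#: matched directly at category level.
TAXONOMY: dict[str, tuple[str, ...]] = {
    "mental illness": (
        "depression",
        "anxiety",
        "PTSD",
        "bipolar",
        "schizophrenia",
    ),
    "substance use": (
        "alcohol use disorder/poisoning",
        "drug use disorder/poisoning",
        "opioid use disorder/poisoning",
        "sedative/hypnotic/anxiolytic use disorder/poisoning",
        "cannabis use disorder",
        "stimulant use disorder/poisoning",
    ),
    "pain": (
        "rheumatoid arthritis/osteoarthritis",
        "migraine/chronic headache",
        "fibromyalgia/chronic pain/fatigue",
    ),
    "chronic disease": (
        "acute MI",
        "heart failure",
        "hypertension",
        "stroke/TIA",
        "asthma",
        "COPD",
        "diabetes",
        "TBI",
        "epilepsy",
        "cancer",
    ),
    "assault": (),
    "suicidal ideation/attempt": ("ideation", "attempt"),
}

CATEGORIES: tuple[str, ...] = tuple(TAXONOMY)

_COMPONENT_PARENT: dict[str, str] = {
    comp: cat for cat, comps in TAXONOMY.items() for comp in comps
}


def _norm_code(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


@dataclass
class CodeMap:
    """Mapping from (category, component) to ICD-9-CM code prefixes.

    ``entries`` rows: (category, component, prefix); component is "" for
    categories matched directly (assault).  Prefixes are stored normalized
    (decimal stripped, uppercase).
    """

    entries: list[tuple[str, str, str]]
    metadata: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("code map is empty")
        seen: set[tuple[str, str]] = set()
        deduped = []
        for cat, comp, prefix in self.entries:
            prefix = _norm_code(prefix)
            if not prefix:
                raise ValueError(f"empty prefix in category {cat!r}")
            if cat not in TAXONOMY:
                raise ValueError(f"unknown exposure category {cat!r}")
            if comp and comp not in TAXONOMY[cat]:
                raise ValueError(
                    f"unknown component {comp!r} for category {cat!r}"
                )
            if not comp and TAXONOMY[cat]:
                raise ValueError(
                    f"category {cat!r} has components; rows must name one"
                )
            key = (comp or cat, prefix)
            if key in seen:
                logger.warning("duplicate code-map row dropped: %s", key)
                continue
            seen.add(key)
            deduped.append((cat, comp, prefix))
        self.entries = deduped

    def prefixes_for(self, label: str) -> tuple[str, ...]:
        """All prefixes for a component, or for a component-less category."""
        return tuple(
            p for cat, comp, p in self.entries if (comp or cat) == label
        )

    def component_labels(self) -> list[str]:
        out: list[str] = []
        for cat, comp, _ in self.entries:
            label = comp or cat
            if comp and label not in out:
                out.append(label)
        return out


def load_code_map(path: str | Path) -> CodeMap:
    """Load a code map from CSV (category, component, prefix) or YAML.

    YAML layout: ``{category: {component: [prefixes]}}`` with a bare list for
    component-less categories.  Leading ``#`` comment lines in the CSV are
    collected into the map's metadata note.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        if not data:
            raise ValueError(f"empty code map: {path}")
        entries = []
        for cat, sub in data.items():
            if isinstance(sub, dict):
                for comp, prefixes in sub.items():
                    entries.extend((cat, comp, str(p)) for p in prefixes)
            else:
                entries.extend((cat, "", str(p)) for p in sub)
        return CodeMap(entries, metadata=f"loaded from {path.name}")

    meta_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                meta_lines.append(line.lstrip("#").strip())
            else:
                break
    table = pd.read_csv(path, comment="#", dtype=str).fillna("")
    if table.empty:
        raise ValueError(f"empty code map: {path}")
    required = {"category", "component", "prefix"}
    if not required.issubset(table.columns):
        raise ValueError(f"code map must have columns {sorted(required)}")
    entries = [
        (r.category, r.component, r.prefix) for r in table.itertuples()
    ]
    return CodeMap(entries, metadata=" ".join(meta_lines))


def default_code_map() -> CodeMap:
    """The packaged illustrative code map (synthetic, non-authoritative).

    Shipped so the pipeline runs end to end; real analyses should supply a
    validated clinical code list through ``load_code_map``.
    """
    return load_code_map(Path(__file__).parent / "data" / "codemap_synthetic.csv")


def _in_window(
    visit_date: pd.Series, death_date: pd.Series, lookback_years: float
) -> pd.Series:
    if float(lookback_years) <= 0:
        raise ValueError("lookback_years must be positive")
    if float(lookback_years).is_integer():
        start = death_date - pd.DateOffset(years=int(lookback_years))
    else:
        start = death_date - pd.DateOffset(months=round(lookback_years * 12))
    return (visit_date >= start) & (visit_date <= death_date)


def code_exposures(
    persons: pd.DataFrame,
    visits: pd.DataFrame,
    code_map: CodeMap | None = None,
    lookback_years: float = 3.0,
) -> pd.DataFrame:
    """Build the person x exposure binary indicator matrix.

    Parameters
    ----------
    persons : table with ``person_id`` and ``death_date`` columns.
    visits : table with ``person_id``, ``visit_date`` and ``codes`` columns;
        ``codes`` holds a list of ICD-9-CM strings (or a single
        semicolon-delimited string).
    code_map : prefix map; the packaged illustrative map when omitted.
    lookback_years : length of the closed lookback window ending at death.

    Returns
    -------
    DataFrame indexed by person_id with ``{0,1}`` columns ``any_visit``, one
    per category, one per component.  Component implies category implies
    any_visit on every row.
    """
    if code_map is None:
        code_map = default_code_map()
    persons = persons.set_index("person_id", drop=False)
    if not persons.index.is_unique:
        raise ValueError("person_id not unique in persons table")

    matrix = pd.DataFrame(
        0,
        index=persons.index,
        columns=["any_visit", *CATEGORIES, *_COMPONENT_PARENT],
        dtype=np.int8,
    )
    matrix.index.name = "person_id"
    if len(visits):
        orphans = set(visits["person_id"]) - set(persons.index)
        if orphans:
            raise ValueError(
                f"visits reference unknown person_ids: {sorted(orphans)[:10]}"
            )
        v = visits.copy()
        v["visit_date"] = pd.to_datetime(v["visit_date"])
        death = persons["death_date"]
        v["death_date"] = pd.to_datetime(v["person_id"].map(death))
        late = v["visit_date"] > v["death_date"]
        if late.any():
            bad = sorted(v.loc[late, "person_id"].unique())[:10]
            raise ValueError(f"visits dated after death for person_ids: {bad}")
        v = v[_in_window(v["visit_date"], v["death_date"], lookback_years)]
        if len(v):
            matrix.loc[v["person_id"].unique(), "any_visit"] = 1
            codes = v["codes"].apply(
                lambda c: c.split(";") if isinstance(c, str) else list(c)
            )
            long = v[["person_id"]].loc[codes.index].copy()
            long["code"] = codes
            long = long.explode("code")
            long["code"] = long["code"].map(_norm_code)
            long = long[long["code"] != ""]
            for cat in CATEGORIES:
                labels = TAXONOMY[cat] or (cat,)
                for label in labels:
                    prefixes = code_map.prefixes_for(label)
                    if not prefixes:
                        continue
                    hit = long.loc[
                        long["code"].str.startswith(prefixes), "person_id"
                    ].unique()
                    if len(hit):
                        col = label if TAXONOMY[cat] else cat
                        matrix.loc[hit, col] = 1
                if TAXONOMY[cat]:
                    matrix[cat] = (
                        matrix[list(TAXONOMY[cat])].max(axis=1).astype(np.int8)
                    )
    return matrix


# Display orders for the descriptive table, matching the cohort taxonomy.
_COVARIATE_LEVELS = {
    "sex": ["female", "male"],
    "education": [
        "high school or less",
        "some college",
        "associates",
        "bachelor",
        "graduate",
        "unknown",
    ],
    "marital_status": [
        "divorced",
        "married/partner",
        "never married",
        "widowed",
        "unknown",
    ],
    "urbanicity": ["large metro", "small metro", "non-metro"],
}


def _pct(count: int, n: int) -> float:
    return round(100.0 * count / n, 1) if n else float("nan")


def summarize_table_one(
    persons: pd.DataFrame, exposures: pd.DataFrame
) -> pd.DataFrame:
    """Descriptive case/control summary: N, age mean (SD), level and flag counts.

    ``persons`` must carry a ``status`` column with values case/control.
    Percentages are ``100 * count / group N`` rounded to one decimal; an
    empty group reports NaN rather than dividing by zero.
    """
    rows = []
    groups = {
        "case": persons[persons["status"] == "case"],
        "control": persons[persons["status"] == "control"],
    }
    ns = {g: len(df) for g, df in groups.items()}
    rec: dict = {"section": "overall", "item": "N"}
    for g in groups:
        rec[f"{g}_n"] = ns[g]
        rec[f"{g}_pct"] = float("nan")
    rows.append(rec)
    rec = {"section": "overall", "item": "age_years mean (SD)"}
    for g, df in groups.items():
        rec[f"{g}_n"] = (
            round(float(df["age_years"].mean()), 1) if len(df) else float("nan")
        )
        rec[f"{g}_pct"] = (
            round(float(df["age_years"].std()), 1) if len(df) > 1 else float("nan")
        )
    rows.append(rec)
    for cov, levels in _COVARIATE_LEVELS.items():
        if cov not in persons.columns:
            continue
        for level in levels:
            rec = {"section": cov, "item": level}
            for g, df in groups.items():
                count = int((df[cov] == level).sum())
                rec[f"{g}_n"] = count
                rec[f"{g}_pct"] = _pct(count, ns[g])
            rows.append(rec)
    flags = [c for c in exposures.columns]
    for flag in flags:
        rec = {"section": "exposures", "item": flag}
        for g, df in groups.items():
            ids = df["person_id"] if "person_id" in df.columns else df.index
            count = int(exposures.loc[exposures.index.intersection(ids), flag].sum())
            rec[f"{g}_n"] = count
            rec[f"{g}_pct"] = _pct(count, ns[g])
        rows.append(rec)
    return pd.DataFrame(rows)
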