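"""Synthetic purchaser-decedent cohorts with known truth.

The restricted linkage data behind the study design (firearm-suicide cases,
motor-vehicle-crash decedent controls, and their hospital/ED visit
histories) cannot be shipped, so this module generates cohorts whose
exposure-outcome odds ratios and control-selection mechanism are known
exactly, making every downstream stage testable.

Generation model, per exposure category (independently across categories):
controls in the eligible pool are exposed with probability
``baseline_prevalence_controls``; the case prevalence is derived from the
control prevalence and the true odds ratio via the logistic identity
``p_case = OR p / (1 - p + OR p)``.  Exposed persons receive at least one
in-window visit carrying a code mapped to that exposure; unexposed persons
receive noise visits with unmapped codes at a configurable rate so the
coder's specificity is exercised.

Differential control selection emulates the deceased-control bias: each
pool control is retained with probability proportional to
``selection_rr ** exposed``, so the selection-proportion ratio
S_control,1 / S_control,0 equals ``selection_rr`` exactly and the crude OR
in the retained sample is biased by the factor 1/selection_rr.  Feeding
``selection_rr`` into the bias analysis as OR_select therefore recovers
the true OR.

Default scale mirrors the study population (3862 cases, 1553 controls).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exposures import CATEGORIES, TAXONOMY, default_code_map

__all__ = [
    "ExposureSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "generate_cohort",
    "apply_selection",
    "simulate_study",
    "write_cohort",
]

_CASE_CODES = ("X72", "X73", "X74")
# plausible occupant/driver MVC underlying causes, all inside the control list
_CONTROL_CODES = ("V435", "V475", "V234", "V892", "V190", "V470", "V485")
_NOISE_CODES = ("4659", "V700", "845.00", "780.6")

_STUDY_START = pd.Timestamp("2008-01-01")
_STUDY_END = pd.Timestamp("2013-12-31")


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure category's generating parameters.

    selection_rr is the relative retention probability of an exposed versus
    unexposed eligible control; benchmark_rate is the exposure rate in the
    living benchmark population (defaults to the pool baseline, i.e. the
    pool itself is representative and all bias comes from retention).
    """

    name: str
    baseline_prevalence_controls: float
    true_or: float
    selection_rr: float = 1.0
    benchmark_rate: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence_controls < 1.0:
            raise ValueError(
                f"{self.name}: baseline prevalence must be in (0,1)"
            )
        if self.true_or <= 0:
            raise ValueError(f"{self.name}: true_or must be positive")
        if self.selection_rr <= 0:
            raise ValueError(f"{self.name}: selection_rr must be positive")

    @property
    def case_prevalence(self) -> float:
        """p_case from the logistic identity p1 = OR p0 / (1 - p0 + OR p0)."""
        p = self.baseline_prevalence_controls
        return self.true_or * p / (1.0 - p + self.true_or * p)


def default_exposure_specs() -> list[ExposureSpec]:
    """Category-level defaults: control prevalences and crude ORs at the
    scale of the study's descriptive table; the only published selection
    ratio (1.71, suicidal ideation/attempt) is used, others default to 1."""
    return [
        ExposureSpec("suicidal ideation/attempt", 0.017, 4.61, selection_rr=1.71),
        ExposureSpec("mental illness", 0.080, 2.07),
        ExposureSpec("substance use", 0.090, 1.24),
        ExposureSpec("pain", 0.070, 1.45),
        ExposureSpec("chronic disease", 0.218, 1.21),
        ExposureSpec("assault", 0.020, 0.45),
    ]


def default_covariate_marginals() -> dict[str, dict[str, float]]:
    return {
        "sex": {"male": 0.913, "female": 0.083, "missing": 0.004},
        "marital_status": {
            "married/partner": 0.434,
            "divorced": 0.234,
            "never married": 0.249,
            "widowed": 0.072,
            "unknown": 0.011,
        },
        "education": {
            "high school or less": 0.407,
            "some college": 0.248,
            "associates": 0.075,
            "bachelor": 0.158,
            "graduate": 0.092,
            "unknown": 0.020,
        },
        "urbanicity": {
            "large metro": 0.680,
            "small metro": 0.250,
            "non-metro": 0.065,
            "missing": 0.005,
        },
    }


@dataclass
class SimulationConfig:
    n_cases: int = 3862
    n_controls_target: int = 1553
    control_pool_multiplier: float = 3.0
    exposure_specs: list[ExposureSpec] = field(default_factory=default_exposure_specs)
    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=default_covariate_marginals
    )
    lookback_years: float = 3.0
    noise_visit_rate: float = 0.30
    confounding: bool = False
    confounding_odds_male: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls_target < 1:
            raise ValueError("n_cases and n_controls_target must be >= 1")
        if self.lookback_years <= 0:
            raise ValueError("lookback_years must be positive")
        if self.control_pool_multiplier < 1.0:
            raise ValueError("control_pool_multiplier must be >= 1")
        for cov, marg in self.covariate_marginals.items():
            total = sum(marg.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"covariate marginal {cov!r} sums to {total}, not 1"
                )
        names = [s.name for s in self.exposure_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate exposure spec names")

    @property
    def n_controls_pool(self) -> int:
        return int(round(self.n_controls_target * self.control_pool_multiplier))


@dataclass
class SimulatedCohort:
    """Generated tables plus the generating truth.

    ``exposures`` is the truth-level indicator matrix (person x spec name,
    plus any_visit), indexed by person_id; the visit-level coder should
    recover it for mapped categories.
    """

    persons: pd.DataFrame
    visits: pd.DataFrame
    exposures: pd.DataFrame
    truth: dict


def _draw_categorical(
    rng: np.random.Generator, marginal: dict[str, float], n: int
) -> np.ndarray:
    levels = list(marginal)
    probs = np.array([marginal[l] for l in levels], dtype=float)
    return rng.choice(levels, size=n, p=probs / probs.sum())


def _truncnorm(rng, mean, sd, lower, n):
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _exposure_probs(
    spec: ExposureSpec, is_case: np.ndarray, male: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    p = np.where(is_case, spec.case_prevalence, spec.baseline_prevalence_controls)
    if config.confounding:
        # shift exposure odds by sex stratum while keeping the case/control
        # odds ratio at true_or within each stratum
        odds = p / (1.0 - p)
        shift = np.where(
            male, config.confounding_odds_male, 1.0 / config.confounding_odds_male
        )
        odds = odds * shift
        p = odds / (1.0 + odds)
    return p


def _category_codes(code_map, name: str) -> list[str]:
    """Concrete undotted codes realizable for one exposure spec name."""
    if name in TAXONOMY and TAXONOMY[name]:
        labels = TAXONOMY[name]
    else:
        labels = (name,)
    codes = []
    for label in labels:
        codes.extend(code_map.prefixes_for(label))
    return codes


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate cases and the pre-selection control pool, with visits.

    Returns persons (cases first, then pool controls), their visit records,
    the truth-level exposure matrix and the generating truth parameters.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    code_map = default_code_map()
    n_case, n_pool = config.n_cases, config.n_controls_pool
    n = n_case + n_pool
    is_case = np.concatenate([np.ones(n_case, bool), np.zeros(n_pool, bool)])

    ids = np.array(
        [f"case-{i:06d}" for i in range(n_case)]
        + [f"ctrl-{i:06d}" for i in range(n_pool)]
    )
    cause = np.concatenate(
        [
            rng.choice(_CASE_CODES, size=n_case),
            rng.choice(_CONTROL_CODES, size=n_pool),
        ]
    )
    covs = {
        cov: _draw_categorical(rng, marg, n)
        for cov, marg in config.covariate_marginals.items()
    }
    # lower truncation at 18 leaves a small under-21 tail for the
    # eligibility filter to exercise
    age = np.where(
        is_case,
        _truncnorm(rng, 56.0, 16.7, 18.0, n),
        _truncnorm(rng, 50.8, 15.8, 18.0, n),
    )
    death_offset_days = rng.integers(0, (_STUDY_END - _STUDY_START).days + 1, size=n)
    death_date = _STUDY_START + pd.to_timedelta(death_offset_days, unit="D")

    persons = pd.DataFrame(
        {
            "person_id": ids,
            "underlying_cause_icd10": cause,
            "death_date": death_date,
            "sex": covs["sex"],
            "age_years": np.round(age, 1),
            "death_year": death_date.year,
            "marital_status": covs["marital_status"],
            "education": covs["education"],
            "urbanicity": covs["urbanicity"],
        }
    )

    male = persons["sex"].to_numpy() == "male"
    expo = pd.DataFrame(index=pd.Index(ids, name="person_id"))
    truth_rows = {}
    for spec in config.exposure_specs:
        p = _exposure_probs(spec, is_case, male, config)
        if min(n_case * spec.case_prevalence,
               n_pool * spec.baseline_prevalence_controls) < 1.0:
            warnings.warn(
                f"{spec.name}: expected exposed count below 1 at this n",
                stacklevel=2,
            )
        expo[spec.name] = (rng.random(n) < p).astype(np.int8)
        p0 = spec.baseline_prevalence_controls
        r = spec.selection_rr
        p_retained = r * p0 / (1.0 - p0 + r * p0)
        benchmark = spec.benchmark_rate if spec.benchmark_rate is not None else p0
        truth_rows[spec.name] = {
            "true_or": spec.true_or,
            "baseline_prevalence_controls": p0,
            "case_prevalence": spec.case_prevalence,
            "selection_rr": r,
            "expected_retained_prevalence": p_retained,
            "benchmark_rate": benchmark,
            "or_select_proportion": r,
            "or_select_benchmark": p_retained / benchmark,
        }

    # visits: one mapped visit per realized exposure, plus noise visits
    lookback_days = int(round(config.lookback_years * 365.25))
    v_pid, v_date, v_codes = [], [], []
    for spec in config.exposure_specs:
        flag = expo[spec.name].to_numpy().astype(bool)
        idx = np.flatnonzero(flag)
        if idx.size == 0:
            continue
        codes = _category_codes(code_map, spec.name)
        chosen = rng.choice(codes, size=idx.size) if codes else np.array([])
        offs = rng.integers(0, lookback_days, size=idx.size)
        v_pid.extend(ids[idx])
        v_date.extend(death_date[idx] - pd.to_timedelta(offs, unit="D"))
        if codes:
            v_codes.extend(chosen)
        else:
            v_codes.extend(["0000"] * idx.size)
    noise = rng.random(n) < config.noise_visit_rate
    idx = np.flatnonzero(noise)
    if idx.size:
        offs = rng.integers(0, lookback_days, size=idx.size)
        v_pid.extend(ids[idx])
        v_date.extend(death_date[idx] - pd.to_timedelta(offs, unit="D"))
        v_codes.extend(rng.choice(_NOISE_CODES, size=idx.size))

    visits = pd.DataFrame(
        {"person_id": v_pid, "visit_date": v_date, "codes": v_codes}
    )
    visits = visits.sort_values(["person_id", "visit_date", "codes"]).reset_index(
        drop=True
    )
    visited = pd.Index(visits["person_id"].unique())
    expo.insert(0, "any_visit", 0)
    expo.loc[expo.index.isin(visited), "any_visit"] = 1
    expo["any_visit"] = expo["any_visit"].astype(np.int8)

    truth = {
        "seed": config.seed,
        "n_cases": n_case,
        "n_controls_pool": n_pool,
        "n_controls_target": config.n_controls_target,
        "confounding": config.confounding,
        "exposures": truth_rows,
    }
    return SimulatedCohort(persons=persons, visits=visits, exposures=expo, truth=truth)


def apply_selection(
    controls: pd.DataFrame,
    exposures: pd.DataFrame,
    specs: list[ExposureSpec],
    n_target: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Differentially retain pool controls, emulating deceased-control bias.

    Each control is kept with probability proportional to the product over
    exposures of ``selection_rr ** indicator``, scaled so the expected
    retained count is ``n_target``.  ``selection_rr = 1`` everywhere is a
    uniform subsample.  Returns the retained control rows.
    """
    for spec in specs:
        if spec.selection_rr <= 0:
            raise ValueError(f"{spec.name}: selection_rr must be positive")
    missing = set(controls["person_id"]) - set(exposures.index)
    if missing:
        raise ValueError(f"controls without exposure rows: {sorted(missing)[:10]}")
    rng = np.random.default_rng(seed)
    x = exposures.loc[controls["person_id"]]
    log_w = np.zeros(len(controls))
    for spec in specs:
        log_w += np.log(spec.selection_rr) * x[spec.name].to_numpy()
    w = np.exp(log_w)
    base = n_target / w.sum()
    prob = np.minimum(1.0, base * w)
    keep = rng.random(len(controls)) < prob
    return controls.loc[keep].copy()


def simulate_study(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort and apply the control-selection mechanism.

    The returned tables contain the cases plus the *retained* controls; the
    truth dict records realized pool and retained counts.
    """
    full = generate_cohort(config)
    is_ctrl = full.persons["person_id"].str.startswith("ctrl-")
    controls = full.persons[is_ctrl]
    retained = apply_selection(
        controls,
        full.exposures,
        config.exposure_specs,
        config.n_controls_target,
        seed=config.seed + 1,
    )
    keep_ids = pd.Index(full.persons.loc[~is_ctrl, "person_id"]).append(
        pd.Index(retained["person_id"])
    )
    persons = full.persons[full.persons["person_id"].isin(keep_ids)].reset_index(
        drop=True
    )
    visits = full.visits[full.visits["person_id"].isin(keep_ids)].reset_index(
        drop=True
    )
    expo = full.exposures.loc[persons["person_id"]]
    truth = dict(full.truth)
    truth["n_controls_retained"] = int(len(retained))
    return SimulatedCohort(persons=persons, visits=visits, exposures=expo, truth=truth)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write persons/visits/exposures as CSV and truth as JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "persons": outdir / "persons.csv",
        "visits": outdir / "visits.csv",
        "exposures": outdir / "exposures.csv",
        "truth": outdir / "truth.json",
    }
    persons = cohort.persons.copy()
    persons["death_date"] = pd.to_datetime(persons["death_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    persons.to_csv(paths["persons"], index=False)
    visits = cohort.visits.copy()
    visits["visit_date"] = pd.to_datetime(visits["visit_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    visits["codes"] = visits["codes"].apply(
        lambda c: c if isinstance(c, str) else ";".join(c)
    )
    visits.to_csv(paths["visits"], index=False)
    cohort.exposures.to_csv(paths["exposures"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
    return paths
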