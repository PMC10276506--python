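"""Logistic-regression hierarchy with robust (sandwich) standard errors.

The case/control outcome is regressed on exposure indicators with a fixed
covariate set: sex, age (continuous years), death year (continuous),
marital status, educational attainment, and county urbanicity.  Two
variants mirror the study design: ``separate`` fits one model per exposure
term (each with the full covariate set) and ``simultaneous`` enters all
terms of a level together.  The same machinery runs at category level and
at disaggregated component level.

Maximum-likelihood estimates come from iteratively reweighted least squares
(statsmodels GLM, binomial family); the covariance is the
heteroskedasticity-consistent sandwich B^-1 M B^-1 with B the expected
information, M the outer product of per-observation scores, and an
HC1-style small-sample factor n/(n-k).  Confidence intervals are Wald on
the log-odds scale.

Reference levels (sex = female, marital = married/partner, education = high
school or less, urbanicity = large metro) are package defaults; "unknown"
is retained as its own level rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exposures import CATEGORIES, TAXONOMY

__all__ = [
    "Z_95",
    "ORResult",
    "LogisticFit",
    "fit_logistic",
    "robust_covariance",
    "build_design",
    "run_hierarchy",
]

#: two-sided 95% normal quantile used throughout for Wald intervals
Z_95 = 1.959964

#: threshold on |log-odds coefficient| beyond which a fit is treated as
#: separated and its estimate marked non-reportable
SEPARATION_COEF = 15.0

COVARIATE_TERMS = (
    "sex",
    "age_years",
    "death_year",
    "marital_status",
    "education",
    "urbanicity",
)

# reference level first; remaining levels become dummies
_LEVELS = {
    "sex": ["female", "male"],
    "marital_status": [
        "married/partner",
        "divorced",
        "never married",
        "widowed",
        "unknown",
    ],
    "education": [
        "high school or less",
        "some college",
        "associates",
        "bachelor",
        "graduate",
        "unknown",
    ],
    "urbanicity": ["large metro", "small metro", "non-metro"],
}


@dataclass
class ORResult:
    """A fitted term's odds ratio with Wald 95% CI and robust log-scale SE."""

    term: str
    or_estimate: float
    ci_low: float
    ci_high: float
    se_ln_or: float
    n_used: int
    model_id: str = ""
    variant: str = "separate"
    estimable: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LogisticFit:
    params: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    colnames: list[str]
    n: int
    converged: bool
    separated: np.ndarray  # boolean per coefficient

    def or_result(self, term: str, **extra) -> ORResult:
        j = self.colnames.index(term)
        b = float(self.params[j])
        se = float(np.sqrt(self.cov_robust[j, j]))
        bad = bool(self.separated[j]) or not self.converged
        return ORResult(
            term=term,
            or_estimate=float(np.exp(b)),
            ci_low=float(np.exp(b - Z_95 * se)),
            ci_high=float(np.exp(b + Z_95 * se)),
            se_ln_or=se,
            n_used=self.n,
            estimable=not bad,
            **extra,
        )


def _validate_design(X: np.ndarray, y: np.ndarray, colnames: list[str]) -> None:
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must contain both classes (0 and 1)")
    zero = np.flatnonzero(~X.any(axis=0))
    if zero.size:
        raise ValueError(
            f"constant-zero design columns: {[colnames[j] for j in zero]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the rank deficiency via QR pivots
        _, r = np.linalg.qr(X)
        small = np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()
        bad = [colnames[j] for j in np.flatnonzero(small)]
        raise ValueError(f"rank-deficient design; collinear columns near {bad}")


def fit_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    colnames: list[str] | None = None,
) -> LogisticFit:
    """Logistic MLE by IRLS with model-based and robust covariance.

    ``X`` must already contain the intercept column.  Convergence: max
    absolute coefficient change below 1e-8 or 100 iterations.  Coefficients
    exceeding the separation threshold are flagged, not raised.
    """
    if isinstance(X, pd.DataFrame):
        colnames = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        colnames = colnames or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    _validate_design(X, y, colnames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100, tol=1e-8, tol_criterion="params")
    params = np.asarray(res.params, dtype=float)
    separated = np.abs(params) > SEPARATION_COEF
    try:
        cov_robust = robust_covariance(X, y, params)
    except ValueError:
        # fitted probabilities at 0/1 (separation): no usable curvature;
        # flag every coefficient non-reportable instead of raising
        cov_robust = np.full((len(params), len(params)), np.nan)
        separated = np.ones_like(separated, dtype=bool)
    return LogisticFit(
        params=params,
        cov_model=np.asarray(res.cov_params(), dtype=float),
        cov_robust=cov_robust,
        colnames=colnames,
        n=len(y),
        converged=bool(res.converged),
        separated=separated,
    )


def robust_covariance(
    X: np.ndarray,
    y: np.ndarray,
    params: np.ndarray,
    small_sample: str = "HC1",
) -> np.ndarray:
    """Sandwich covariance B^-1 M B^-1 for a fitted logistic model.

    B is the expected (= observed, for canonical-link logistic) information
    X' W X with W = diag(p(1-p)); M is the outer product of per-observation
    scores x_i (y_i - p_i).  ``small_sample`` selects the finite-sample
    factor: "HC1" multiplies by n/(n-k), "HC0" applies none.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    params = np.asarray(params, dtype=float)
    n, k = X.shape
    p = 1.0 / (1.0 + np.exp(-X @ params))
    w = p * (1.0 - p)
    bread = X.T @ (X * w[:, None])
    try:
        bread_inv = np.linalg.inv(bread)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular information (bread) matrix") from err
    scores = X * (y - p)[:, None]
    meat = scores.T @ scores
    cov = bread_inv @ meat @ bread_inv
    if small_sample == "HC1":
        cov = cov * (n / (n - k))
    elif small_sample != "HC0":
        raise ValueError(f"unknown small_sample flavor {small_sample!r}")
    return (cov + cov.T) / 2.0


def build_design(
    persons: pd.DataFrame,
    exposures: pd.DataFrame,
    terms: list[str],
    covariates: bool = True,
) -> pd.DataFrame:
    """Assemble the model matrix: intercept, exposure terms, covariate dummies.

    Categorical covariates are expanded against the package reference levels;
    dummy columns for levels absent from the data are dropped (they would be
    structurally zero).
    """
    idx = persons["person_id"] if "person_id" in persons.columns else persons.index
    design = pd.DataFrame({"intercept": 1.0}, index=pd.Index(idx, name="person_id"))
    expo = exposures.loc[design.index]
    for t in terms:
        design[t] = expo[t].astype(float).to_numpy()
    if covariates:
        p = persons.set_index(pd.Index(idx, name="person_id"))
        design["male"] = (p["sex"] == "male").astype(float)
        design["age_years"] = p["age_years"].astype(float)
        design["death_year"] = p["death_year"].astype(float)
        for cov in ("marital_status", "education", "urbanicity"):
            for level in _LEVELS[cov][1:]:
                col = f"{cov}[{level}]"
                vals = (p[cov] == level).astype(float)
                if vals.any():
                    design[col] = vals
    return design


def _fit_terms(
    persons: pd.DataFrame,
    exposures: pd.DataFrame,
    terms: list[str],
    model_id: str,
    variant: str,
    covariates: bool,
) -> list[ORResult]:
    y = (persons["status"] == "case").astype(float).to_numpy()
    design = build_design(persons, exposures, terms, covariates=covariates)
    try:
        fit = fit_logistic(design, y)
    except (ValueError, np.linalg.LinAlgError):
        return [
            ORResult(t, np.nan, np.nan, np.nan, np.nan, len(y),
                     model_id=model_id, variant=variant, estimable=False)
            for t in terms
        ]
    return [
        fit.or_result(t, model_id=model_id, variant=variant) for t in terms
    ]


def run_hierarchy(
    persons: pd.DataFrame,
    exposures: pd.DataFrame,
    variant: str = "separate",
    terms: list[str] | None = None,
    covariates: bool = True,
) -> pd.DataFrame:
    """Fit the model hierarchy and return one ORResult row per exposure term.

    ``variant="separate"`` fits one adjusted model per term;
    ``variant="simultaneous"`` enters all terms in a single adjusted model;
    ``variant="components"`` runs both variants within each category over
    that category's disaggregated components.  Terms default to the six
    categories.  Models failing the separation or estimability checks are
    reported with ``estimable=False`` and the run continues.
    """
    if variant == "components":
        rows: list[ORResult] = []
        for cat in CATEGORIES:
            comps = [c for c in TAXONOMY[cat] if c in exposures.columns]
            if not comps:
                continue
            for v in ("separate", "simultaneous"):
                sub = run_hierarchy(
                    persons, exposures, variant=v, terms=comps,
                    covariates=covariates,
                )
                sub["model_id"] = f"{cat}:" + sub["model_id"]
                rows.append(sub)
        return pd.concat(rows, ignore_index=True)

    if terms is None:
        terms = [c for c in CATEGORIES if c in exposures.columns]
    if not terms:
        raise ValueError("no exposure terms to model")
    if variant == "separate":
        results = []
        for t in terms:
            results.extend(
                _fit_terms(persons, exposures, [t], f"separate[{t}]",
                           "separate", covariates)
            )
    elif variant == "simultaneous":
        results = _fit_terms(
            persons, exposures, list(terms), "simultaneous", "simultaneous",
            covariates,
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return pd.DataFrame([r.to_dict() for r in results])
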