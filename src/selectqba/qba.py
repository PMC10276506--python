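"""Probabilistic quantitative selection-bias analysis for deceased controls.

In a case-control study whose controls are themselves decedents, inclusion
depends on cause of death; if exposure predicts the control-defining cause,
exposed controls are over- (or under-) represented and the observed odds
ratio is biased.  The bias factor is

    OR_select = (S_case,0 * S_control,1) / (S_case,1 * S_control,0)

with S a selection proportion, indexing exposed/unexposed by 1/0.  When all
cases are selected (the default assumption) this reduces to
S_control,1 / S_control,0, and in the absence of known selection
probabilities it is benchmarked by the ratio of the exposure rate among
sampled controls to the rate in a living reference population.

The bias-adjusted estimate multiplies the observed (covariate-adjusted)
odds ratio by OR_select.  Uncertainty in the bias parameter is represented
by a triangular prior with mode OR_select and limits 20% below/above the
mode (on the OR scale); random error enters through the standard error of
the observed log odds ratio.  Each Monte Carlo iteration draws

    OR_total_error = exp( ln(OR_observed * T) + Z * SE(ln OR_observed) )

with T triangular and Z standard normal.  The median of the draws is the
bias-adjusted OR and the 2.5th/97.5th percentiles form the 95% simulation
interval, which reflects both systematic bias and random error.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "se_from_ci",
    "or_select",
    "or_select_from_proportions",
    "or_select_from_benchmark",
    "sample_triangular",
    "SelectionProportions",
    "QBAInputs",
    "QBAResult",
    "qba_simulate",
    "qba_batch",
    "derive_seed",
]

_MIN_ITER = 1000


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Recover SE(ln OR) from a printed Wald confidence interval.

    ``(ln ci_high - ln ci_low) / (2 z)``; the inverse of CI construction on
    the log-odds scale.  Raises for non-positive or zero-width limits.
    """
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("confidence limits must be positive")
    if ci_high <= ci_low:
        raise ValueError("need ci_low < ci_high")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return (np.log(ci_high) - np.log(ci_low)) / (2.0 * z)


@dataclass(frozen=True)
class SelectionProportions:
    """Selection probabilities by outcome (case/control) and exposure (1/0)."""

    s_control_1: float
    s_control_0: float
    s_case_1: float = 1.0
    s_case_0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("s_case_1", "s_case_0", "s_control_1", "s_control_0"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")


def or_select_from_proportions(sel: SelectionProportions) -> float:
    """OR_select = (S_case,0 * S_control,1) / (S_case,1 * S_control,0)."""
    return (sel.s_case_0 * sel.s_control_1) / (sel.s_case_1 * sel.s_control_0)


def or_select_from_benchmark(
    rate_controls_sample: float, rate_benchmark_population: float
) -> float:
    """Benchmark form: sampled-control exposure rate over living-population rate.

    Only the ratio matters, so any common unit (percent, per-1000) is fine.
    """
    if rate_controls_sample <= 0 or rate_benchmark_population <= 0:
        raise ValueError("benchmark rates must be positive")
    return rate_controls_sample / rate_benchmark_population


def or_select(
    sel: SelectionProportions | None = None,
    rate_controls_sample: float | None = None,
    rate_benchmark_population: float | None = None,
) -> float:
    """Compute OR_select from selection proportions or a benchmark rate pair."""
    if sel is not None:
        return or_select_from_proportions(sel)
    if rate_controls_sample is None or rate_benchmark_population is None:
        raise ValueError("supply SelectionProportions or both benchmark rates")
    return or_select_from_benchmark(rate_controls_sample, rate_benchmark_population)


def sample_triangular(
    mode: float,
    lower: float,
    upper: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw from a triangular distribution; degenerates to a point mass.

    ``lower == mode == upper`` returns a constant sample; ``lower > upper``
    (or a mode outside the limits) raises.
    """
    if lower > upper:
        raise ValueError("triangular requires lower <= upper")
    if not lower <= mode <= upper:
        raise ValueError("triangular mode must lie within [lower, upper]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lower == upper:
        return np.full(n, float(mode))
    return rng.triangular(lower, mode, upper, size=n)


@dataclass
class QBAInputs:
    """Summary-level inputs for one exposure's bias analysis.

    ``se_ln_or`` is derived from the confidence interval when not supplied;
    ``rel_lower``/``rel_upper`` are relative half-widths of the triangular
    prior on the OR scale (default 20% either side of the mode).
    """

    or_observed: float
    ci_low: float
    ci_high: float
    or_select_mode: float
    se_ln_or: float | None = None
    rel_lower: float = 0.20
    rel_upper: float = 0.20
    n_iter: int = 50_000
    seed: int = 0
    exposure: str = ""

    def __post_init__(self) -> None:
        if self.or_observed <= 0 or self.or_select_mode <= 0:
            raise ValueError("odds ratios must be positive")
        if not self.ci_low < self.or_observed < self.ci_high:
            raise ValueError("need ci_low < or_observed < ci_high")
        if not 0.0 <= self.rel_lower < 1.0 or self.rel_upper < 0.0:
            raise ValueError("relative limits must satisfy 0 <= rel_lower < 1")
        if self.n_iter < _MIN_ITER:
            raise ValueError(
                f"n_iter={self.n_iter} < {_MIN_ITER}: tail percentiles unstable"
            )
        if self.se_ln_or is None:
            self.se_ln_or = se_from_ci(self.ci_low, self.ci_high)
        elif self.se_ln_or < 0:
            raise ValueError("se_ln_or must be non-negative")


@dataclass
class QBAResult:
    """Bias-adjusted OR with its 95% simulation interval."""

    or_adjusted_point: float  # or_observed * or_select_mode, no random error
    median: float             # median of the total-error draws
    si_low: float
    si_high: float
    n_iter: int
    seed: int
    exposure: str = ""
    draws: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "or_adjusted_point": self.or_adjusted_point,
            "median": self.median,
            "si_low": self.si_low,
            "si_high": self.si_high,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


def qba_simulate(inputs: QBAInputs, keep_draws: bool = False) -> QBAResult:
    """Monte Carlo propagation of the selection-bias prior and random error.

    Per iteration: T ~ triangular(mode(1-rel_lower), mode, mode(1+rel_upper)),
    Z ~ N(0,1); emit exp(ln(OR_observed * T) + Z * SE(ln OR_observed)).
    Fixed seed gives bit-reproducible draws and percentiles (linear
    interpolation between order statistics).
    """
    rng = np.random.default_rng(inputs.seed)
    mode = inputs.or_select_mode
    t = sample_triangular(
        mode,
        mode * (1.0 - inputs.rel_lower),
        mode * (1.0 + inputs.rel_upper),
        inputs.n_iter,
        seed=rng,
    )
    z = rng.standard_normal(inputs.n_iter)
    draws = np.exp(np.log(inputs.or_observed * t) + z * inputs.se_ln_or)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return QBAResult(
        or_adjusted_point=inputs.or_observed * mode,
        median=float(np.median(draws)),
        si_low=float(lo),
        si_high=float(hi),
        n_iter=inputs.n_iter,
        seed=inputs.seed,
        exposure=inputs.exposure,
        draws=draws if keep_draws else None,
    )


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic, order-independent per-exposure seed below 2**31.

    Mixes the master seed with a CRC-32 of the exposure label through a
    SeedSequence, so batch results do not depend on row order.
    """
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def qba_batch(
    inputs_table: pd.DataFrame,
    n_iter: int = 50_000,
    master_seed: int = 0,
    rel_lower: float = 0.20,
    rel_upper: float = 0.20,
) -> pd.DataFrame:
    """Run the bias analysis for a table of exposures.

    ``inputs_table`` columns: exposure, or_observed, ci_low, ci_high,
    or_select_mode, optionally rel_lower/rel_upper per row.  Each exposure
    gets an independent seed derived from the master seed and its label.
    Returns one row per exposure with observed and bias-adjusted summaries,
    suitable for a paired observed-vs-adjusted forest plot.
    """
    labels = list(inputs_table["exposure"])
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate exposure labels in QBA input table")
    rows = []
    for rec in inputs_table.to_dict("records"):
        inp = QBAInputs(
            or_observed=float(rec["or_observed"]),
            ci_low=float(rec["ci_low"]),
            ci_high=float(rec["ci_high"]),
            or_select_mode=float(rec["or_select_mode"]),
            rel_lower=float(rec.get("rel_lower", rel_lower) or rel_lower),
            rel_upper=float(rec.get("rel_upper", rel_upper) or rel_upper),
            n_iter=n_iter,
            seed=derive_seed(master_seed, str(rec["exposure"])),
            exposure=str(rec["exposure"]),
        )
        res = qba_simulate(inp)
        row = res.to_dict()
        row.update(
            or_observed=inp.or_observed,
            ci_low=inp.ci_low,
            ci_high=inp.ci_high,
            or_select_mode=inp.or_select_mode,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def forest_plot(batch: pd.DataFrame, path=None):
    """Paired forest plot of observed vs bias-adjusted ORs on a log axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # stable ids so repeated renders are byte-identical
    matplotlib.rcParams["svg.hashsalt"] = "selectqba"

    n = len(batch)
    obs = batch["or_observed"].to_numpy(float)
    lo, hi = batch["ci_low"].to_numpy(float), batch["ci_high"].to_numpy(float)
    med = batch["median"].to_numpy(float)
    slo, shi = batch["si_low"].to_numpy(float), batch["si_high"].to_numpy(float)
    fig, ax = plt.subplots(figsize=(7, 1 + 0.6 * n))
    ypos = np.arange(n)[::-1].astype(float)
    ax.errorbar(
        obs, ypos + 0.15, xerr=[obs - lo, hi - obs],
        fmt="o", color="tab:gray", label="observed (95% CI)", capsize=2,
    )
    ax.errorbar(
        med, ypos - 0.15, xerr=[med - slo, shi - med],
        fmt="s", color="tab:blue", label="bias-adjusted (95% SI)", capsize=2,
    )
    ax.axvline(1.0, color="k", lw=0.8, ls=":")
    ax.set_xscale("log")
    ax.set_yticks(ypos)
    ax.set_yticklabels(batch["exposure"])
    ax.set_xlabel("odds ratio (log scale)")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
        return None
    return fig
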