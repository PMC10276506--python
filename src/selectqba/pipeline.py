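"""End-to-end orchestration: simulate/ingest -> cohort -> exposures ->
models -> QBA -> report, with a reproducibility manifest.

All randomness flows from a single master seed; every stage writes
deterministic artifacts, so rerunning with an unchanged config produces
byte-identical outputs and checksums.  A QBA-only run from a hand-written
summary CSV (observed ORs with CIs plus a selection-bias mode per exposure)
is supported without any microdata.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import apply_eligibility, classify_persons
from .exposures import code_exposures, load_code_map, summarize_table_one
from .models import run_hierarchy
from .qba import forest_plot, qba_batch
from .synth import SimulationConfig, ExposureSpec, simulate_study, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_report"]

_ALL_STAGES = ("simulate", "cohort", "exposures", "models", "qba", "report")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = _ALL_STAGES
    # external inputs (used instead of the simulate stage's outputs)
    persons_path: str | None = None
    visits_path: str | None = None
    codemap_path: str | None = None
    qba_inputs_path: str | None = None
    # stage settings
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    lookback_years: float = 3.0
    min_age: float = 21.0
    model_variants: tuple[str, ...] = ("separate", "simultaneous")
    qba_n_iter: int = 50_000
    qba_rel_lower: float = 0.20
    qba_rel_upper: float = 0.20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages and "cohort" in self.stages:
            if not self.persons_path:
                raise ValueError("cohort stage enabled but no persons input")
            if not Path(self.persons_path).exists():
                raise FileNotFoundError(self.persons_path)
        if "qba" in self.stages and "models" not in self.stages:
            if not self.qba_inputs_path:
                raise ValueError("qba stage without models needs qba_inputs_path")
            if not Path(self.qba_inputs_path).exists():
                raise FileNotFoundError(self.qba_inputs_path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: dict, stage: str, paths: dict, counts: dict | None = None) -> None:
    manifest["stages"][stage] = {
        "artifacts": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                      for k, p in paths.items()},
        "counts": counts or {},
    }


def _simulation_config(config: RunConfig) -> SimulationConfig:
    overrides = dict(config.simulate)
    if "exposure_specs" in overrides:
        overrides["exposure_specs"] = [
            ExposureSpec(**s) for s in overrides["exposure_specs"]
        ]
    overrides.setdefault("lookback_years", config.lookback_years)
    return SimulationConfig(seed=config.seed, **overrides)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    Any stage failure raises with the stage named.  Returns the manifest
    dict (also written to ``<out_dir>/manifest.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "settings": {
            "lookback_years": config.lookback_years,
            "min_age": config.min_age,
            "model_variants": list(config.model_variants),
            "qba_n_iter": config.qba_n_iter,
            "qba_rel_lower": config.qba_rel_lower,
            "qba_rel_upper": config.qba_rel_upper,
        },
    }
    persons = visits = exposures = None
    truth = None
    model_results: pd.DataFrame | None = None

    stage = "inputs"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            cohort = simulate_study(_simulation_config(config))
            paths = write_cohort(cohort, out / "simulate")
            persons, visits = cohort.persons, cohort.visits
            truth = cohort.truth
            _record(manifest, stage, paths, {
                "persons": len(persons), "visits": len(visits),
            })
        elif config.persons_path:
            persons = pd.read_csv(config.persons_path, parse_dates=["death_date"])
            if config.visits_path:
                visits = pd.read_csv(config.visits_path, parse_dates=["visit_date"])

        if "cohort" in config.stages:
            stage = "cohort"
            classified = classify_persons(persons)
            n_ineligible = int((classified["status"] == "ineligible").sum())
            eligible = classified[classified["status"] != "ineligible"]
            retained, report = apply_eligibility(eligible, min_age=config.min_age)
            cdir = out / "cohort"
            cdir.mkdir(exist_ok=True)
            ppath = cdir / "persons_retained.csv"
            retained.assign(
                death_date=pd.to_datetime(retained["death_date"]).dt.strftime("%Y-%m-%d")
            ).to_csv(ppath, index=False)
            rpath = cdir / "eligibility.json"
            payload = report.to_dict()
            payload["n_ineligible_cause"] = n_ineligible
            rpath.write_text(json.dumps(payload, indent=2, sort_keys=True))
            persons = retained
            _record(manifest, stage, {"persons_retained": ppath, "eligibility": rpath},
                    payload | {"n_retained": report.n_retained})

        if "exposures" in config.stages:
            stage = "exposures"
            code_map = (
                load_code_map(config.codemap_path) if config.codemap_path else None
            )
            stage_visits = (
                visits if visits is not None
                else pd.DataFrame(columns=["person_id", "visit_date", "codes"])
            )
            # visits of persons excluded upstream are dropped, not orphaned
            stage_visits = stage_visits[
                stage_visits["person_id"].isin(persons["person_id"])
            ]
            exposures = code_exposures(
                persons, stage_visits, code_map,
                lookback_years=config.lookback_years,
            )
            edir = out / "exposures"
            edir.mkdir(exist_ok=True)
            xpath = edir / "exposure_matrix.csv"
            exposures.to_csv(xpath)
            t1 = summarize_table_one(persons, exposures)
            tpath = edir / "table1.csv"
            t1.to_csv(tpath, index=False)
            _record(manifest, stage, {"exposure_matrix": xpath, "table1": tpath},
                    {"persons": len(exposures)})

        if "models" in config.stages:
            stage = "models"
            frames = [
                run_hierarchy(persons, exposures, variant=v)
                for v in config.model_variants
            ]
            model_results = pd.concat(frames, ignore_index=True)
            mdir = out / "models"
            mdir.mkdir(exist_ok=True)
            mpath = mdir / "or_results.csv"
            model_results.to_csv(mpath, index=False)
            _record(manifest, stage, {"or_results": mpath},
                    {"models": len(model_results)})

        if "qba" in config.stages:
            stage = "qba"
            if config.qba_inputs_path:
                qin = pd.read_csv(config.qba_inputs_path)
            else:
                sep = model_results[
                    (model_results["variant"] == "separate")
                    & model_results["estimable"]
                ]
                modes = {
                    name: row["or_select_proportion"]
                    for name, row in (truth or {}).get("exposures", {}).items()
                }
                qin = pd.DataFrame({
                    "exposure": sep["term"],
                    "or_observed": sep["or_estimate"],
                    "ci_low": sep["ci_low"],
                    "ci_high": sep["ci_high"],
                    "or_select_mode": [modes.get(t, 1.0) for t in sep["term"]],
                })
            results = qba_batch(
                qin, n_iter=config.qba_n_iter, master_seed=config.seed,
                rel_lower=config.qba_rel_lower, rel_upper=config.qba_rel_upper,
            )
            qdir = out / "qba"
            qdir.mkdir(exist_ok=True)
            qpath = qdir / "qba_results.csv"
            results.to_csv(qpath, index=False)
            fpath = qdir / "forest.svg"
            forest_plot(results, fpath)
            _record(manifest, stage, {"qba_results": qpath, "forest": fpath},
                    {"exposures": len(results)})
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if "report" in config.stages:
        report_path = render_report(manifest, out)
        manifest["stages"]["report"] = {
            "artifacts": {"report": {"path": str(report_path),
                                     "sha256": _sha256(report_path)}},
            "counts": {},
        }
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _fmt_or_table(df: pd.DataFrame) -> str:
    lines = ["| term | variant | OR | 95% CI | robust SE(ln OR) | n |",
             "|---|---|---|---|---|---|"]
    for r in df.itertuples():
        if r.estimable:
            lines.append(
                f"| {r.term} | {r.variant} | {r.or_estimate:.2f} "
                f"| {r.ci_low:.2f}, {r.ci_high:.2f} | {r.se_ln_or:.4f} | {r.n_used} |"
            )
        else:
            lines.append(
                f"| {r.term} | {r.variant} | non-estimable* | — | — | {r.n_used} |"
            )
    if not df["estimable"].all():
        lines.append("")
        lines.append("\\* flagged by the separation/estimability check; "
                     "reported, not dropped.")
    return "\n".join(lines)


def render_report(manifest: dict, out_dir: str | Path) -> Path:
    """Render a human-readable markdown report from a run's artifacts.

    Sections for stages absent from the manifest are marked as not run
    rather than failing.
    """
    out = Path(out_dir)
    stages = manifest.get("stages", {})
    parts = [
        "# selectqba run report",
        "",
        f"- package version: {manifest.get('version')}",
        f"- master seed: {manifest.get('seed')}",
        f"- settings: `{json.dumps(manifest.get('settings', {}), sort_keys=True)}`",
        "",
    ]
    if "cohort" in stages:
        c = stages["cohort"]["counts"]
        parts += [
            "## Cohort eligibility",
            "",
            f"- input: {c.get('n_input')}  (ineligible cause of death removed "
            f"upstream: {c.get('n_ineligible_cause', 0)})",
            f"- excluded, under-age: {c.get('n_excluded_age')}",
            f"- excluded, missing sex/urbanicity: {c.get('n_excluded_missing')}",
            f"- retained: {c.get('n_retained')}",
            "",
        ]
    else:
        parts += ["## Cohort eligibility", "", "_stage not run_", ""]
    if "exposures" in stages:
        t1 = pd.read_csv(stages["exposures"]["artifacts"]["table1"]["path"])
        parts += ["## Descriptive summary (cases vs controls)", "",
                  t1.to_markdown(index=False), ""]
    else:
        parts += ["## Descriptive summary", "", "_stage not run_", ""]
    if "models" in stages:
        res = pd.read_csv(stages["models"]["artifacts"]["or_results"]["path"])
        parts += ["## Adjusted odds ratios", "", _fmt_or_table(res), ""]
    else:
        parts += ["## Adjusted odds ratios", "", "_stage not run_", ""]
    if "qba" in stages:
        q = pd.read_csv(stages["qba"]["artifacts"]["qba_results"]["path"])
        lines = ["| exposure | observed OR (95% CI) | OR_select mode "
                 "| bias-adjusted OR (95% SI) |", "|---|---|---|---|"]
        for r in q.itertuples():
            lines.append(
                f"| {r.exposure} | {r.or_observed:.2f} ({r.ci_low:.2f}, "
                f"{r.ci_high:.2f}) | {r.or_select_mode:.2f} "
                f"| {r.median:.2f} ({r.si_low:.2f}, {r.si_high:.2f}) |"
            )
        parts += ["## Quantitative selection-bias analysis", "",
                  "\n".join(lines), "",
                  "Paired forest plot: `qba/forest.svg` (log scale).", ""]
    else:
        parts += ["## Quantitative selection-bias analysis", "",
                  "_stage not run_", ""]
    path = out / "report.md"
    path.write_text("\n".join(parts))
    return path
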