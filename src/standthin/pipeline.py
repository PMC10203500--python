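"""End-to-end orchestration: simulate -> thin -> measure -> fit -> report.

`run_pipeline` executes the full factorial defined by a YAML scenario
config, writing all stage outputs as delimited text plus a JSON run
manifest.  Numeric tables carry no timestamps, so identical reruns are
byte-stable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .standtable import StandTrajectory, ValidationError, write_tree_table
from .thinning import ThinningEvent, PRE_COMMERCIAL, COMMERCIAL
from .synthetic import GrowthParams, ScenarioConfig, TreatmentSpec, default_factorial, simulate_scenario
from .maturity import stand_quantitative_maturity, volume_series, fit_richards
from .productivity import (
    pai_table,
    relation_points,
    scenario_report,
    structure_metrics_table,
    structure_productivity_fit,
)
from .volume import merchantable_table

log = logging.getLogger("standthin")

__all__ = ["RunManifest", "load_config", "run_pipeline"]


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    outputs: dict = field(default_factory=dict)
    version: str = "0.1.0"
    started: str = ""
    finished: str = ""
    failed_stage: str | None = None

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path | None) -> tuple[ScenarioConfig, GrowthParams]:
    """Load a YAML scenario config; missing keys fall back to the shipped
    experimental-design defaults (the seven-treatment factorial)."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    growth_keys = {f.name for f in fields(GrowthParams)}
    params = GrowthParams(**{k: v for k, v in raw.get("growth", {}).items() if k in growth_keys})
    sc = raw.get("scenario", {})
    if "treatments" in sc:
        treatments = []
        for t in sc["treatments"]:
            events = tuple(
                ThinningEvent(int(e["age"]), float(e["residual_density"]), e.get("kind", PRE_COMMERCIAL))
                for e in t.get("events", [])
            )
            treatments.append(TreatmentSpec(t["name"], events))
    else:
        treatments = default_factorial().treatments
    config = ScenarioConfig(
        treatments=treatments,
        planting_density=float(sc.get("planting_density", 5000)),
        area_ha=float(sc.get("area_ha", 0.04)),
        start_age=int(sc.get("start_age", 4)),
        end_age=int(sc.get("end_age", 32)),
        replicates=int(sc.get("replicates", 3)),
        base_seed=int(sc.get("base_seed", 1)),
    )
    return config, params


def _maturity_table(trajectories: list[StandTrajectory]) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        series = volume_series(traj)
        fit = fit_richards(series.ages, series.values)
        qma = stand_quantitative_maturity(traj)
        rows.append(
            {
                "plot_id": traj.plot_id,
                "treatment": traj.treatment,
                "qma": qma if qma is not None else "",
                "richards_a": fit.params.a if fit.params else np.nan,
                "richards_b": fit.params.b if fit.params else np.nan,
                "richards_c": fit.params.c if fit.params else np.nan,
                "r_squared": fit.r_squared,
                "rmse": fit.rmse,
                "sv_final": series.values[-1],
            }
        )
    return pd.DataFrame(rows)


def _volume_table(trajectories: list[StandTrajectory]) -> pd.DataFrame:
    from .volume import stand_volume, stand_volume_with_thinned

    rows = []
    for traj in trajectories:
        for snap in traj.snapshots:
            merch = merchantable_table(snap)
            rows.append(
                {
                    "plot_id": traj.plot_id,
                    "treatment": traj.treatment,
                    "stand_age": snap.stand_age,
                    "sv_existing": stand_volume(snap),
                    "sv_total": stand_volume_with_thinned(traj, snap.stand_age),
                    "merch_small": merch["volume"]["small"],
                    "merch_medium": merch["volume"]["medium"],
                    "merch_large": merch["volume"]["large"],
                    "merch_sub": merch["sub_volume"],
                }
            )
    return pd.DataFrame(rows)


def _relation_table(trajectories: list[StandTrajectory], seed: int) -> pd.DataFrame:
    rows = []
    for kind, prefix in ((PRE_COMMERCIAL, "TE"), (COMMERCIAL, "TL")):
        trts = sorted({t.treatment for t in trajectories if t.treatment.startswith(prefix)})
        if not trts:
            continue
        pts = relation_points(trajectories, treatments=trts, group_label=kind)
        if len(pts) < 3 or pts["gc"].nunique() < 2:
            continue
        fit = structure_productivity_fit(pts, seed=seed)
        rows.append(
            {
                "scenario": kind,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "ci_low": fit.slope_ci[0],
                "ci_high": fit.slope_ci[1],
                "n_points": fit.n,
            }
        )
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config_path: str | Path | None, output_dir: str | Path) -> RunManifest:
    """Run the full analysis and write every stage output under ``output_dir``.

    Stages: simulate the factorial, write the tree list, per-snapshot
    structure metrics, volume and merchantable tables, Richards fits and
    maturity ages, PAI and the structure-productivity relation, and a
    treatment-level summary.  Any stage failure is recorded in the manifest
    with the failing stage name.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config, params = load_config(config_path)
    if config.replicates < 1:
        raise ValidationError("replicates must be >= 1")
    manifest = RunManifest(
        config={"scenario": {"replicates": config.replicates, "base_seed": config.base_seed,
                             "planting_density": config.planting_density, "area_ha": config.area_ha,
                             "start_age": config.start_age, "end_age": config.end_age,
                             "treatments": [t.name for t in config.treatments]},
                "growth": asdict(params)},
        seeds={"base_seed": config.base_seed, "bootstrap_seed": config.base_seed},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stage = "simulate"
    try:
        t0 = time.time()
        trajectories = simulate_scenario(config, params)
        log.info("simulate: %d plots in %.1fs", len(trajectories), time.time() - t0)

        stage = "tree_list"
        tree_path = out / "tree_list.csv"
        write_tree_table(trajectories, tree_path)
        manifest.outputs["tree_list"] = str(tree_path)

        stage = "metrics"
        _write(structure_metrics_table(trajectories), out / "structure_metrics.csv")
        manifest.outputs["structure_metrics"] = str(out / "structure_metrics.csv")

        stage = "volumes"
        _write(_volume_table(trajectories), out / "volumes.csv")
        manifest.outputs["volumes"] = str(out / "volumes.csv")

        stage = "maturity"
        _write(_maturity_table(trajectories), out / "maturity.csv")
        manifest.outputs["maturity"] = str(out / "maturity.csv")

        stage = "productivity"
        _write(pai_table(trajectories), out / "pai.csv")
        manifest.outputs["pai"] = str(out / "pai.csv")
        rel = _relation_table(trajectories, seed=config.base_seed)
        _write(rel, out / "structure_productivity.csv")
        manifest.outputs["structure_productivity"] = str(out / "structure_productivity.csv")

        stage = "report"
        report = scenario_report(trajectories)
        _write(report, out / "treatment_summary.csv")
        manifest.outputs["treatment_summary"] = str(out / "treatment_summary.csv")
    except Exception:
        manifest.failed_stage = stage
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.save(out / "manifest.json")
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(out / "manifest.json")
    log.info("pipeline complete: %d outputs", len(manifest.outputs))
    return manifest
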