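"""End-to-end experiment drivers: single-scenario validation-style runs
and the wall-elasticity sweep, with file artifacts and structured logs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import (
    IndicesReport,
    ImpedanceSpectrum,
    SweepResult,
    compute_indices,
    elasticity_sweep,
    input_impedance,
)
from .scenarios import ExperimentConfig, build_scenario_model, default_peripheral
from .simulate import SimulationResult, simulate

__all__ = ["ScenarioRun", "run_scenario", "run_sweep"]

logger = logging.getLogger(__name__)


@dataclass
class ScenarioRun:
    scenario: str
    result: SimulationResult
    indices: IndicesReport
    impedance: ImpedanceSpectrum


def _monotone(values, direction: str, rel_slack: float = 1e-3) -> bool:
    v = np.asarray(values, dtype=float)
    slack = rel_slack * max(float(np.max(np.abs(v))), 1e-12)
    d = np.diff(v)
    return bool(np.all(d >= -slack)) if direction == "nondecreasing" else bool(
        np.all(d <= slack)
    )


def run_scenario(
    config: ExperimentConfig, scenario: Optional[str] = None, write: bool = True
) -> ScenarioRun:
    """Build, simulate and analyse one catalogued scenario.

    Writes ``<scenario>_result.csv``, ``<scenario>_indices.json`` and
    ``<scenario>_zin.csv`` under ``config.output_dir``.  Outputs are a pure
    function of the config, so repeated runs are byte-identical.
    """
    label = scenario or config.scenarios[0]
    logger.info("stage=build scenario=%s", label)
    inflow = config.inflow.realise()
    peripheral = default_peripheral(inflow, config.mean_pressure, config.outlet_pressure)
    model = build_scenario_model(label, peripheral)
    logger.info("stage=simulate scenario=%s", label)
    result = simulate(model, inflow, config.solver)
    logger.info(
        "stage=converge scenario=%s cycles=%d converged=%s",
        label,
        result.cycles_run,
        result.converged,
    )
    logger.info("stage=analyze scenario=%s", label)
    indices = compute_indices(result, model)
    zin = input_impedance(result.p_tl, result.q_i)
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = label.replace(",", "_")
        result.write_csv(outdir / f"{tag}_result.csv")
        (outdir / f"{tag}_indices.json").write_text(
            json.dumps(indices.to_dict(), indent=2, sort_keys=True)
        )
        zin.to_frame().to_csv(outdir / f"{tag}_zin.csv", index=False, float_format="%.12g")
    return ScenarioRun(scenario=label, result=result, indices=indices, impedance=zin)


def run_sweep(config: ExperimentConfig, write: bool = True) -> tuple[pd.DataFrame, dict]:
    """Elasticity sweep over the configured scenarios.

    Returns the combined tidy table and a summary holding, per scenario,
    the min/max of each index over the factor grid, monotonicity verdicts
    for pulse pressure (non-decreasing with stiffness) and the index of
    direction (non-increasing), and the ID span; when both reference
    scenarios are swept the summary also reports which has the wider ID
    span.
    """
    inflow = config.inflow.realise()
    peripheral = default_peripheral(inflow, config.mean_pressure, config.outlet_pressure)
    tables = []
    summary: dict = {"scenarios": {}}
    for label in config.scenarios:
        logger.info("stage=sweep scenario=%s factors=%d", label, len(config.sweep_factors))
        model = build_scenario_model(label, peripheral)
        sweep: SweepResult = elasticity_sweep(model, inflow, config.sweep_factors, config.solver)
        tables.append(sweep.table)
        t = sweep.table
        per: dict = {"failures": sweep.failures}
        for metric in sorted(t["metric"].unique()):
            vals = t[t["metric"] == metric]["value"]
            per[metric] = {"min": float(vals.min()), "max": float(vals.max())}
        factors = sorted(sweep.reports)
        pp_prox_tl = [sweep.reports[f].pressures["proximal"]["tl"].pp for f in factors]
        pp_prox_fl = [sweep.reports[f].pressures["proximal"]["fl"].pp for f in factors]
        per["pp_tl_nondecreasing"] = _monotone(pp_prox_tl, "nondecreasing")
        per["pp_fl_nondecreasing"] = _monotone(pp_prox_fl, "nondecreasing")
        ids = [
            sweep.reports[f].direction_index
            for f in factors
            if sweep.reports[f].direction_index is not None
        ]
        if ids:
            per["id_nonincreasing"] = _monotone(ids, "nonincreasing")
            per["id_span"] = float(max(ids) - min(ids))
        summary["scenarios"][label] = per
    spans = {
        s: d.get("id_span") for s, d in summary["scenarios"].items() if d.get("id_span") is not None
    }
    if len(spans) >= 2:
        summary["widest_id_span"] = max(spans, key=lambda s: spans[s])
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "sweep_table.csv", index=False, float_format="%.12g")
        (outdir / "sweep_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return table, summary
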