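"""Derived haemodynamic quantities: pressure indices, false-lumen pressure
index, peak time shift, index of direction, tear velocities, input
impedance and the wall-elasticity sweep.

Site/pressure mapping: the circuit has exactly four pressure nodes, read as
proximal TL = ``p_tl``, proximal FL = ``p_fl``, distal FL = ``p_dt`` and
distal TL = ``p_ph``.

The index of direction compares the two tear flows in the TL->FL sense:
``ID = |Q_PT + Q_DT| / (|Q_PT| + |Q_DT|)`` with ``Q_DT = -Q_FL`` (the
simulator's axial FL flow is positive toward the outlet).  ID = 1 means
both tears pass flow into (or out of) the FL together — side-chamber
behaviour; ID = 0 means what enters proximally leaves distally — two
parallel vessels.  The instantaneous ratio is aggregated over the cycle as
a ratio of integrals, which is bounded and robust at zero crossings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DissectionModelSpec
from .simulate import SimulationResult, SolverSettings, simulate
from .waveforms import PeriodicWaveform

__all__ = [
    "PressureIndex",
    "IndicesReport",
    "ImpedanceSpectrum",
    "pressure_indices",
    "fpi",
    "tsf",
    "index_of_direction",
    "tear_velocity",
    "input_impedance",
    "compute_indices",
    "elasticity_sweep",
    "SweepResult",
    "DEFAULT_SWEEP_FACTORS",
]

DEFAULT_SWEEP_FACTORS = (0.35, 1.0, 10.0, 1e2, 1e3, 1e4, 1e5, 1e6, 1e7)

SITE_SIGNALS = {
    "proximal": {"tl": "p_tl", "fl": "p_fl"},
    "distal": {"tl": "p_ph", "fl": "p_dt"},
}


class AnalysisError(ValueError):
    """Raised for undefined indices (flat signals, zero denominators)."""


def _require_converged(result: SimulationResult, force: bool) -> None:
    if not result.converged and not force:
        raise AnalysisError(
            "simulation did not reach periodic steady state; pass force=True to analyse anyway"
        )


@dataclass(frozen=True)
class PressureIndex:
    sp: float  # systolic (cycle max), mmHg
    dp: float  # diastolic (cycle min), mmHg

    @property
    def pp(self) -> float:
        return self.sp - self.dp


def pressure_indices(result: SimulationResult, force: bool = False) -> dict:
    """SP/DP/PP per site and lumen from discrete extrema on the output grid."""
    _require_converged(result, force)
    out: dict = {}
    for site, lumens in SITE_SIGNALS.items():
        out[site] = {}
        for lumen, signal in lumens.items():
            series = getattr(result, signal)
            out[site][lumen] = PressureIndex(sp=float(series.max()), dp=float(series.min()))
    return out


def fpi(result: SimulationResult, force: bool = False) -> dict:
    """False-lumen pressure index: FL systolic/diastolic pressure as a
    percentage of the TL value, per site."""
    idx = pressure_indices(result, force)
    out = {}
    for site, lumens in idx.items():
        if lumens["tl"].sp == 0.0 or lumens["tl"].dp == 0.0:
            raise AnalysisError(f"FPI undefined at {site}: zero TL pressure")
        out[site] = {
            "systolic": 100.0 * lumens["fl"].sp / lumens["tl"].sp,
            "diastolic": 100.0 * lumens["fl"].dp / lumens["tl"].dp,
        }
    return out


def _circular_delay(t_fl: float, t_tl: float, period: float) -> float:
    """Circular difference t_fl - t_tl mapped to (-T/2, T/2]."""
    d = (t_fl - t_tl) % period
    if d > period / 2.0:
        d -= period
    return d


def tsf(result: SimulationResult, period: Optional[float] = None, force: bool = False) -> dict:
    """Time shift of the FL systolic peak relative to the TL peak, per site.

    Positive values mean the FL peak arrives later.  Ties resolve to the
    earliest sample; a flat waveform has no peak and raises.
    """
    _require_converged(result, force)
    T = period if period is not None else result.period
    out = {}
    for site, lumens in SITE_SIGNALS.items():
        times = {}
        for lumen, signal in lumens.items():
            series = getattr(result, signal)
            if np.ptp(series) == 0.0:
                raise AnalysisError(f"TSF undefined at {site}: flat {lumen} pressure")
            times[lumen] = float(result.time[int(np.argmax(series))])
        out[site] = _circular_delay(times["fl"], times["tl"], T)
    return out


def index_of_direction(q_pt: Sequence[float], q_dt: Sequence[float]) -> float:
    """Index of direction of the two tear flows, both oriented TL->FL.

    Cycle-integral aggregation of ``|Q_PT + Q_DT| / (|Q_PT| + |Q_DT|)``;
    lies in [0, 1].  Undefined (raises) if both series are identically zero.
    """
    q_pt = np.asarray(q_pt, dtype=float)
    q_dt = np.asarray(q_dt, dtype=float)
    if q_pt.shape != q_dt.shape:
        raise AnalysisError("tear-flow series must share one grid")
    denom = float(np.sum(np.abs(q_pt) + np.abs(q_dt)))
    if denom == 0.0:
        raise AnalysisError("index of direction undefined: both tear flows identically zero")
    return float(np.sum(np.abs(q_pt + q_dt)) / denom)


def tear_velocity(
    q_tear: Sequence[float], diameter: float, obstruction_fraction: float = 0.25
) -> np.ndarray:
    """Mean velocity through a tear orifice (m/s) from flow in ml/s.

    ``obstruction_fraction`` shrinks the effective area, emulating the
    cross-section blocked by a measuring catheter (0 for the pure model
    output; 0.25 reproduces the catheterised-bench comparison convention).
    """
    if not (0.0 <= obstruction_fraction < 1.0):
        raise AnalysisError(f"obstruction_fraction must lie in [0, 1), got {obstruction_fraction}")
    if not (diameter > 0.0):
        raise AnalysisError(f"tear diameter must be positive, got {diameter}")
    area = (1.0 - obstruction_fraction) * math.pi * (diameter / 2.0) ** 2
    return np.asarray(q_tear, dtype=float) * 1e-6 / area


@dataclass
class ImpedanceSpectrum:
    """Input impedance over harmonics 0..K: modulus (mmHg s/ml), phase
    (radians), plus the inlet-pressure power spectrum.  Harmonics whose
    flow coefficient vanishes are flagged undefined instead of infinite."""

    harmonics: np.ndarray
    modulus: np.ndarray
    phase: np.ndarray
    pressure_power: np.ndarray
    defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "harmonic": self.harmonics,
                "modulus_mmHg_s_ml": self.modulus,
                "phase_rad": self.phase,
                "pressure_power_mmHg2": self.pressure_power,
                "defined": self.defined,
            }
        )


def input_impedance(
    p_in: PeriodicWaveform | Sequence[float],
    q_in: PeriodicWaveform | Sequence[float],
    n_harmonics: int = 10,
) -> ImpedanceSpectrum:
    """Input impedance Zin_k = P_k / Q_k for harmonics k = 0..n_harmonics.

    ``p_in`` and ``q_in`` must sample the same single period on a common
    uniform grid.  The pressure power spectrum is the one-sided power of the
    pressure harmonics (|c_0|^2 at DC, 2|c_k|^2 above).
    """
    p = p_in.samples if isinstance(p_in, PeriodicWaveform) else np.asarray(p_in, dtype=float)
    q = q_in.samples if isinstance(q_in, PeriodicWaveform) else np.asarray(q_in, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise AnalysisError("pressure and flow series must share one uniform grid")
    n = p.size
    if n < 2 * n_harmonics + 2:
        raise AnalysisError(
            f"{n} samples cannot resolve {n_harmonics} harmonics (need >= {2 * n_harmonics + 2})"
        )
    pk = np.fft.rfft(p)[: n_harmonics + 1] / n
    qk = np.fft.rfft(q)[: n_harmonics + 1] / n
    scale = float(np.max(np.abs(qk)))
    defined = np.abs(qk) > max(scale, 1e-300) * 1e-12
    z = np.full(n_harmonics + 1, np.nan + 0j)
    z[defined] = pk[defined] / qk[defined]
    power = np.abs(pk) ** 2
    power[1:] *= 2.0
    return ImpedanceSpectrum(
        harmonics=np.arange(n_harmonics + 1),
        modulus=np.abs(z),
        phase=np.where(defined, np.angle(z), np.nan),
        pressure_power=power,
        defined=defined,
    )


# --------------------------------------------------------------------------
# full per-run report and the elasticity sweep


@dataclass
class IndicesReport:
    """All per-run haemodynamic indices."""

    scenario: str
    pressures: dict  # site -> lumen -> PressureIndex
    fpi: dict  # site -> {"systolic": %, "diastolic": %}
    tsf: dict  # site -> s
    direction_index: Optional[float]  # None when only one tear exists
    peak_tear_velocity: dict = field(default_factory=dict)  # site -> m/s

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "pressures_mmHg": {
                site: {
                    lumen: {"sp": pi.sp, "dp": pi.dp, "pp": pi.pp}
                    for lumen, pi in lumens.items()
                }
                for site, lumens in self.pressures.items()
            },
            "fpi_percent": self.fpi,
            "tsf_s": self.tsf,
            "index_of_direction": self.direction_index,
            "peak_tear_velocity_m_s": self.peak_tear_velocity,
        }


def compute_indices(
    result: SimulationResult,
    model: Optional[DissectionModelSpec] = None,
    obstruction_fraction: float = 0.0,
    force: bool = False,
) -> IndicesReport:
    """Assemble the full index report for one converged simulation.

    The index of direction needs both tear flows and is reported only for
    two-tear models; tear velocities need the tear diameters carried by
    ``model`` and default to the pure (unobstructed) orifice area.
    """
    pres = pressure_indices(result, force)
    both_tears = bool(np.any(result.q_pt != 0.0)) and bool(np.any(result.q_fl != 0.0))
    if model is not None:
        both_tears = model.has_proximal_tear and model.has_distal_tear
    di = None
    if both_tears:
        di = index_of_direction(result.q_pt, -result.q_fl)
    velocities = {}
    if model is not None:
        if model.proximal_tear is not None and model.proximal_tear.diameter:
            v = tear_velocity(result.q_pt, model.proximal_tear.diameter, obstruction_fraction)
            velocities["proximal"] = float(np.max(np.abs(v)))
        if model.distal_tear is not None and model.distal_tear.diameter:
            v = tear_velocity(result.q_fl, model.distal_tear.diameter, obstruction_fraction)
            velocities["distal"] = float(np.max(np.abs(v)))
    return IndicesReport(
        scenario=result.scenario_id,
        pressures=pres,
        fpi=fpi(result, force),
        tsf=tsf(result, force=force),
        direction_index=di,
        peak_tear_velocity=velocities,
    )


@dataclass
class SweepResult:
    table: pd.DataFrame
    reports: dict  # factor -> IndicesReport
    results: dict  # factor -> SimulationResult
    failures: dict  # factor -> error message


def _report_rows(scenario: str, factor: float, report: IndicesReport) -> list[dict]:
    rows = []

    def add(metric, value, site=None, lumen=None):
        rows.append(
            {
                "scenario": scenario,
                "factor": factor,
                "metric": metric,
                "site": site,
                "lumen": lumen,
                "value": value,
            }
        )

    for site, lumens in report.pressures.items():
        for lumen, pi in lumens.items():
            add("sp", pi.sp, site, lumen)
            add("dp", pi.dp, site, lumen)
            add("pp", pi.pp, site, lumen)
    for site, vals in report.fpi.items():
        add("fpi_systolic", vals["systolic"], site)
        add("fpi_diastolic", vals["diastolic"], site)
    for site, val in report.tsf.items():
        add("tsf", val, site)
    if report.direction_index is not None:
        add("id", report.direction_index)
    for site, val in report.peak_tear_velocity.items():
        add("peak_tear_velocity", val, site)
    return rows


def elasticity_sweep(
    model: DissectionModelSpec,
    inflow: PeriodicWaveform,
    factors: Sequence[float] = DEFAULT_SWEEP_FACTORS,
    settings: Optional[SolverSettings] = None,
    obstruction_fraction: float = 0.0,
) -> SweepResult:
    """Scale both walls' Young's moduli by each factor and re-simulate.

    Factor 1 reproduces the reference model; large factors approach the
    rigid-wall limit.  Per-factor failures are recorded and the sweep
    continues.  Returns a tidy long-format table plus the raw per-factor
    reports and simulation results.
    """
    rows: list[dict] = []
    reports: dict = {}
    results: dict = {}
    failures: dict = {}
    warm: Optional[np.ndarray] = None
    for factor in factors:
        scaled = model.with_elasticity_factor(factor)
        try:
            res = simulate(scaled, inflow, settings, initial_state=warm)
            report = compute_indices(res, scaled, obstruction_fraction)
        except Exception as exc:  # noqa: BLE001 - sweep must survive per-factor failures
            failures[factor] = str(exc)
            continue
        warm = res.final_state
        reports[factor] = report
        results[factor] = res
        rows.extend(_report_rows(model.scenario_id, factor, report))
    return SweepResult(
        table=pd.DataFrame(rows), reports=reports, results=results, failures=failures
    )
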