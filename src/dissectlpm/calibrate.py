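"""Two-stage parameter estimation against measured pressure waveforms.

Stage 1 fits, simultaneously on the two distal-single-tear scenarios
(S_0,4 and S_0,10), the parameters shared by every scenario — the TL
compliance and the small/large tear resistances — together with each
scenario's own FL compliance.  Stage 2 then fits only the FL compliance of
any remaining scenario with the shared parameters frozen.

The objective is the sum over the available pressure observables of the
raw (un-normalised) root-mean-square error between predicted and measured
waveforms; the relative rRMSE (normalised by the measured peak-to-peak) is
computed for reporting only.  The simplex search runs in log-space, which
enforces positivity and spans the decades the parameters live on.
Starting points come from a deterministic coarse log-grid scan (three
points per decade, one cyclic coordinate-descent pass) around geometric
first guesses, followed by three Nelder-Mead starts; the best objective
wins, ties broken by start order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import (
    DissectionModelSpec,
    WallProperties,
    lumen_compliance,
    young_modulus_from_compliance,
)
from .scenarios import (
    FL_GEOMETRY,
    TL_GEOMETRY,
    build_scenario_model,
    parse_scenario,
)
from .simulate import SolverSettings, dc_steady_state, simulate
from .waveforms import OBSERVABLE_SIGNALS, PeriodicWaveform

__all__ = [
    "CalibrationTargets",
    "CalibrationResult",
    "rrmse",
    "objective",
    "fit_stage1",
    "fit_stage2",
    "Stage1Result",
]

logger = logging.getLogger(__name__)

#: objective value returned for a failed candidate simulation
PENALTY = 1.0e6

#: default solver settings used inside the search loop (quiet on the
#: non-convergence of throwaway candidates; the returned fit is re-checked)
CALIBRATION_SOLVER = SolverSettings(rtol=1e-6, atol=1e-8, warn_on_nonconvergence=False)


class CalibrationError(ValueError):
    pass


def rrmse(predicted: PeriodicWaveform | np.ndarray, measured: PeriodicWaveform | np.ndarray) -> float:
    """Relative RMSE in percent: 100 * RMSE(pred - meas) / ptp(meas).

    The normalisation by the measured peak-to-peak keeps the metric on the
    pulse scale; a constant measured signal has no pulse and raises.
    """
    pred = predicted.samples if isinstance(predicted, PeriodicWaveform) else np.asarray(predicted, float)
    meas = measured.samples if isinstance(measured, PeriodicWaveform) else np.asarray(measured, float)
    if pred.shape != meas.shape:
        raise CalibrationError("waveforms must share one grid (resample first)")
    span = float(np.ptp(meas))
    if span == 0.0:
        raise CalibrationError("rRMSE undefined for a constant measured signal")
    return 100.0 * float(np.sqrt(np.mean((pred - meas) ** 2))) / span


@dataclass
class CalibrationTargets:
    """Measured (or fixture) pressure waveforms for one scenario plus the
    matched inflow.  Observable keys follow the tear layout: a site is
    measurable only where its tear exists."""

    scenario: str
    inflow: PeriodicWaveform
    pressures: Mapping[str, PeriodicWaveform]

    def __post_init__(self) -> None:
        parse_scenario(self.scenario)
        if not self.pressures:
            raise CalibrationError(f"{self.scenario}: no pressure observables supplied")
        for key, wf in self.pressures.items():
            if key not in OBSERVABLE_SIGNALS:
                raise CalibrationError(f"unknown observable {key!r}")
            if abs(wf.period - self.inflow.period) > 1e-9 * self.inflow.period:
                raise CalibrationError(f"{key}: period differs from the inflow period")


def _predicted_series(result, key: str, n: int) -> np.ndarray:
    series = getattr(result, OBSERVABLE_SIGNALS[key])
    if series.size != n:
        wf = PeriodicWaveform(series, result.period, "pressure")
        return wf.resample(n).samples
    return series


def _sum_rmse(model: DissectionModelSpec, targets: CalibrationTargets,
              settings: SolverSettings) -> float:
    """Simulate a candidate model and sum raw RMSEs over the observables."""
    try:
        warm = dc_steady_state(model, targets.inflow.mean()).as_state()
        result = simulate(model, targets.inflow, settings, initial_state=warm)
    except Exception as exc:  # noqa: BLE001 - failed candidates get a finite penalty
        logger.warning("candidate simulation failed (%s): %s", model.scenario_id, exc)
        return PENALTY
    total = 0.0
    with np.errstate(over="ignore", invalid="ignore"):
        for key, wf in targets.pressures.items():
            pred = _predicted_series(result, key, wf.n_samples)
            total += float(np.sqrt(np.mean((pred - wf.samples) ** 2)))
    if not np.isfinite(total):
        return PENALTY
    return total


def objective(
    params: Mapping[str, float],
    targets: CalibrationTargets,
    peripheral,
    settings: Optional[SolverSettings] = None,
) -> float:
    """Objective for one scenario: candidate ``params`` may carry ``c_tl``,
    ``c_fl``, ``r_small``, ``r_large``; unspecified entries keep their
    catalogue values."""
    settings = settings or CALIBRATION_SOLVER
    tears = None
    if "r_small" in params or "r_large" in params:
        from .scenarios import TEAR_RESISTANCES

        tears = dict(TEAR_RESISTANCES)
        tears.update({k[2:]: v for k, v in params.items() if k in ("r_small", "r_large")})
    model = build_scenario_model(
        targets.scenario,
        peripheral,
        c_tl=params.get("c_tl"),
        c_fl=params.get("c_fl"),
        tear_resistances=tears,
    )
    return _sum_rmse(model, targets, settings)


# --------------------------------------------------------------------------
# deterministic start-point generation

#: scan ranges (clinical units), three points per decade
_SCAN_RANGES = {"compliance": (1e-4, 1.0), "resistance": (0.05, 10.0)}


def _scan_axis(kind: str) -> np.ndarray:
    lo, hi = _SCAN_RANGES[kind]
    n = int(round(3 * np.log10(hi / lo))) + 1
    return np.logspace(np.log10(lo), np.log10(hi), n)


def _coordinate_scan(fun: Callable[[np.ndarray], float], x0: np.ndarray,
                     kinds: Sequence[str]) -> tuple[np.ndarray, float]:
    """One cyclic pass of coordinate descent over the coarse log grids."""
    x = x0.copy()
    best = fun(x)
    for i, kind in enumerate(kinds):
        for value in np.log(_scan_axis(kind)):
            cand = x.copy()
            cand[i] = value
            f = fun(cand)
            if f < best:
                best, x = f, cand
    return x, best


def _multistart_simplex(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    kinds: Sequence[str],
    tol: float,
    maxfev: Optional[int],
    n_starts: int = 3,
):
    """Coarse scan then ``n_starts`` deterministic Nelder-Mead runs."""
    x_scan, _ = _coordinate_scan(fun, x0, kinds)
    shift = np.log(10.0) / 3.0
    starts = [x_scan, x_scan + shift, x_scan - shift][:n_starts]
    budget = maxfev if maxfev is not None else 400 * len(x0)
    best = None
    nfev = 0
    for start in starts:
        res = None
        x = start
        # restarting from the collapsed simplex escapes the narrow curved
        # valleys of strongly correlated parameter pairs
        for _ in range(4):
            prev = res.fun if res is not None else np.inf
            res = minimize(
                fun,
                x,
                method="Nelder-Mead",
                options={"xatol": tol, "fatol": tol, "maxfev": budget},
            )
            nfev += res.nfev
            x = res.x
            if prev - res.fun <= max(tol, 1e-12 * abs(prev)):
                break
        if best is None or res.fun < best.fun:
            best = res
    return best, nfev


@dataclass
class Stage1Result:
    """Shared parameters plus per-scenario FL compliances from stage 1."""

    c_tl: float
    c_fl: dict  # scenario -> ml/mmHg
    r_small: float
    r_large: float
    e_tl_pa: float
    e_fl_pa: dict
    objective: float
    rrmse_percent: dict  # scenario -> observable -> %
    n_eval: int
    converged: bool


@dataclass
class CalibrationResult:
    """Stage-2 result: the FL compliance of one scenario."""

    scenario: str
    c_fl: float
    e_fl_pa: float
    objective: float
    rrmse_percent: dict
    n_eval: int
    converged: bool


def _report_rrmse(model, targets: CalibrationTargets, settings) -> dict:
    warm = dc_steady_state(model, targets.inflow.mean()).as_state()
    result = simulate(model, targets.inflow, settings, initial_state=warm)
    return {
        key: rrmse(_predicted_series(result, key, wf.n_samples), wf.samples)
        for key, wf in targets.pressures.items()
    }


def _geometric_compliance_guess(geometry) -> float:
    # thin-wall compliance at a 1 MPa modulus: an order-of-magnitude anchor
    return lumen_compliance(geometry, WallProperties(1.0e6))


def fit_stage1(
    targets_small: CalibrationTargets,
    targets_large: CalibrationTargets,
    peripheral,
    settings: Optional[SolverSettings] = None,
    tol: float = 1e-6,
    maxfev: Optional[int] = None,
    n_starts: int = 3,
) -> Stage1Result:
    """Simultaneous simplex fit on the two distal-single-tear scenarios.

    ``targets_small`` must be the small-distal-tear scenario (S_0,4) and
    ``targets_large`` the large one (S_0,10); the small/large tear
    resistances are identified from them respectively.  Returns shared
    C_TL, R_small, R_large and both FL compliances, with moduli derived
    from the geometry.  Non-convergence returns the best point found,
    flagged.
    """
    settings = settings or CALIBRATION_SOLVER
    for tg, expect in ((targets_small, 4), (targets_large, 10)):
        p, d = parse_scenario(tg.scenario)
        if p != 0 or d != expect:
            raise CalibrationError(
                f"stage 1 expects S_0,4 and S_0,10 targets, got {tg.scenario}"
            )

    kinds = ("compliance", "compliance", "compliance", "resistance", "resistance")

    def unpack(x):
        c_tl, c_fl_s, c_fl_l, r_small, r_large = np.exp(x)
        return c_tl, c_fl_s, c_fl_l, r_small, r_large

    def fun(x):
        c_tl, c_fl_s, c_fl_l, r_small, r_large = unpack(x)
        tears = {"small": r_small, "large": r_large}
        total = 0.0
        for tg, c_fl in ((targets_small, c_fl_s), (targets_large, c_fl_l)):
            model = build_scenario_model(
                tg.scenario, peripheral, c_tl=c_tl, c_fl=c_fl, tear_resistances=tears
            )
            total += _sum_rmse(model, tg, settings)
        return total

    x0 = np.log(
        [
            _geometric_compliance_guess(TL_GEOMETRY),
            _geometric_compliance_guess(FL_GEOMETRY),
            _geometric_compliance_guess(FL_GEOMETRY),
            0.5,
            0.5,
        ]
    )
    best, nfev = _multistart_simplex(fun, x0, kinds, tol, maxfev, n_starts)
    c_tl, c_fl_s, c_fl_l, r_small, r_large = unpack(best.x)
    tears = {"small": r_small, "large": r_large}
    rrmse_out = {}
    for tg, c_fl in ((targets_small, c_fl_s), (targets_large, c_fl_l)):
        model = build_scenario_model(
            tg.scenario, peripheral, c_tl=c_tl, c_fl=c_fl, tear_resistances=tears
        )
        rrmse_out[tg.scenario] = _report_rrmse(model, tg, settings)
    return Stage1Result(
        c_tl=c_tl,
        c_fl={targets_small.scenario: c_fl_s, targets_large.scenario: c_fl_l},
        r_small=r_small,
        r_large=r_large,
        e_tl_pa=young_modulus_from_compliance(TL_GEOMETRY, c_tl),
        e_fl_pa={
            targets_small.scenario: young_modulus_from_compliance(FL_GEOMETRY, c_fl_s),
            targets_large.scenario: young_modulus_from_compliance(FL_GEOMETRY, c_fl_l),
        },
        objective=float(best.fun),
        rrmse_percent=rrmse_out,
        n_eval=nfev,
        converged=bool(best.success),
    )


def fit_stage2(
    targets: CalibrationTargets,
    c_tl: float,
    r_small: float,
    r_large: float,
    peripheral,
    settings: Optional[SolverSettings] = None,
    tol: float = 1e-6,
    maxfev: Optional[int] = None,
    n_starts: int = 3,
) -> CalibrationResult:
    """One-dimensional simplex fit of a scenario's FL compliance with the
    shared stage-1 parameters frozen."""
    settings = settings or CALIBRATION_SOLVER
    tears = {"small": r_small, "large": r_large}

    def fun(x):
        model = build_scenario_model(
            targets.scenario, peripheral, c_tl=c_tl, c_fl=float(np.exp(x[0])),
            tear_resistances=tears,
        )
        return _sum_rmse(model, targets, settings)

    x0 = np.log([_geometric_compliance_guess(FL_GEOMETRY)])
    best, nfev = _multistart_simplex(fun, x0, ("compliance",), tol, maxfev, n_starts)
    c_fl = float(np.exp(best.x[0]))
    model = build_scenario_model(
        targets.scenario, peripheral, c_tl=c_tl, c_fl=c_fl, tear_resistances=tears
    )
    return CalibrationResult(
        scenario=targets.scenario,
        c_fl=c_fl,
        e_fl_pa=young_modulus_from_compliance(FL_GEOMETRY, c_fl),
        objective=float(best.fun),
        rrmse_percent={targets.scenario: _report_rrmse(model, targets, settings)},
        n_eval=nfev,
        converged=bool(best.success),
    )
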