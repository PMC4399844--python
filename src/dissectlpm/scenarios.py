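"""Scenario catalogue and experiment configuration.

Eight anatomic scenarios ``S_p,d`` cover the permutations of tear size
(4 mm small / 10 mm large), number (one or two) and position (proximal /
distal); the subscript 0 marks an absent tear.  Each scenario carries the
bench-calibrated parameter set: the two tear resistances, a common TL
compliance, and a per-scenario FL compliance (each FL phantom piece was
custom made, so its wall modulus differs between scenarios).

The recorded TL Young's modulus (1.07 MPa) and the fitted TL compliance
(0.0016 ml/mmHg) are not mutually consistent under the thin-wall formula
for the stated geometry; the fitted compliance is the operative value and
the modulus is kept as descriptive metadata only.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .core import (
    DissectionModelSpec,
    FluidProperties,
    LumenGeometry,
    PeripheralBed,
    WATER_25C,
    build_model,
    parse_scenario,
)
from .simulate import SolverSettings
from .waveforms import PeriodicWaveform, read_waveform, synth_inflow

__all__ = [
    "TL_GEOMETRY",
    "FL_GEOMETRY",
    "FLUID",
    "TEAR_RESISTANCES",
    "C_TL",
    "FL_COMPLIANCES",
    "SCENARIOS",
    "scenario_catalogue",
    "build_scenario_model",
    "default_peripheral",
    "InflowSpec",
    "ExperimentConfig",
]

TL_GEOMETRY = LumenGeometry(inner_radius=0.008, wall_thickness=0.002, length=0.16)
FL_GEOMETRY = LumenGeometry(inner_radius=0.01615, wall_thickness=0.001, length=0.16)
FLUID: FluidProperties = WATER_25C

#: fitted tear resistances (mmHg s/ml) by size class
TEAR_RESISTANCES = {"small": 2.2200, "large": 0.1434}

#: common fitted TL compliance (ml/mmHg); E_TL metadata = 1.07 MPa
C_TL = 0.0016
E_TL_METADATA_PA = 1.07e6

#: per-scenario fitted FL compliance (ml/mmHg) and wall modulus (Pa)
FL_COMPLIANCES = {
    "S_4,0": 0.1110,
    "S_10,0": 0.1760,
    "S_0,4": 0.1427,
    "S_0,10": 0.2735,
    "S_4,4": 0.1011,
    "S_4,10": 0.1480,
    "S_10,4": 0.2813,
    "S_10,10": 0.1700,
}
FL_YOUNG_MODULI_PA = {
    "S_4,0": 3.82e6,
    "S_10,0": 2.41e6,
    "S_0,4": 2.97e6,
    "S_0,10": 1.55e6,
    "S_4,4": 4.19e6,
    "S_4,10": 2.86e6,
    "S_10,4": 1.51e6,
    "S_10,10": 2.49e6,
}

SCENARIOS = tuple(FL_COMPLIANCES)


@dataclass(frozen=True)
class ScenarioParameters:
    label: str
    proximal_mm: int
    distal_mm: int
    c_tl: float
    c_fl: float
    e_fl_pa: float


def scenario_catalogue() -> dict[str, ScenarioParameters]:
    """The eight catalogued scenarios with their calibrated parameters."""
    out = {}
    for label in SCENARIOS:
        p, d = parse_scenario(label)
        out[label] = ScenarioParameters(
            label=label,
            proximal_mm=p,
            distal_mm=d,
            c_tl=C_TL,
            c_fl=FL_COMPLIANCES[label],
            e_fl_pa=FL_YOUNG_MODULI_PA[label],
        )
    return out


def default_peripheral(
    inflow: PeriodicWaveform, mean_pressure: float = 100.0, outlet_pressure: float = 0.0
) -> PeripheralBed:
    """Peripheral resistance from a target mean pressure over the mean
    inflow (the bench value was set the same way: mean outlet pressure over
    mean outflow); outlet pressure defaults to venous zero."""
    q_mean = inflow.mean()
    if q_mean <= 0.0:
        raise ValueError("mean inflow must be positive to size the peripheral resistance")
    return PeripheralBed(
        resistance=(mean_pressure - outlet_pressure) / q_mean, outlet_pressure=outlet_pressure
    )


def build_scenario_model(
    label: str,
    peripheral: PeripheralBed,
    c_tl: Optional[float] = None,
    c_fl: Optional[float] = None,
    tear_resistances: Optional[dict] = None,
) -> DissectionModelSpec:
    """Build a catalogued scenario's circuit, optionally overriding the
    calibrated compliances / tear resistances (used by the fitting code)."""
    label = f"S_{parse_scenario(label)[0]},{parse_scenario(label)[1]}"
    if label not in FL_COMPLIANCES:
        raise KeyError(f"scenario {label} not in catalogue")
    from .core import WallProperties

    return build_model(
        scenario=label,
        tl_geometry=TL_GEOMETRY,
        fl_geometry=FL_GEOMETRY,
        tl_wall=WallProperties(E_TL_METADATA_PA),
        fl_wall=WallProperties(FL_YOUNG_MODULI_PA[label]),
        tear_resistances=tear_resistances or TEAR_RESISTANCES,
        peripheral=peripheral,
        fluid=FLUID,
        tl_compliance=C_TL if c_tl is None else c_tl,
        fl_compliance=FL_COMPLIANCES[label] if c_fl is None else c_fl,
    )


# --------------------------------------------------------------------------
# serialisable experiment configuration


@dataclass
class InflowSpec:
    """Inlet waveform source: synthesised or read from CSV."""

    source: str = "synth"  # "synth" | "file"
    period: float = 1.0
    peak_flow: float = 250.0
    systolic_fraction: float = 0.35
    diastolic_leak: float = 10.0
    n_samples: int = 1024
    n_harmonics: int = 12
    path: Optional[str] = None

    def realise(self) -> PeriodicWaveform:
        if self.source == "synth":
            return synth_inflow(
                period=self.period,
                peak_flow=self.peak_flow,
                systolic_fraction=self.systolic_fraction,
                diastolic_leak=self.diastolic_leak,
                n_samples=self.n_samples,
                n_harmonics=self.n_harmonics,
            )
        if self.source == "file":
            if not self.path:
                raise ValueError("inflow source 'file' requires a path")
            return read_waveform(self.path, "flow")
        raise ValueError(f"unknown inflow source {self.source!r}")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a run: scenarios, inflow, solver
    settings, sweep factors, peripheral sizing, output directory, seed."""

    scenarios: Sequence[str] = ("S_4,4", "S_10,10")
    inflow: InflowSpec = field(default_factory=InflowSpec)
    solver: SolverSettings = field(default_factory=SolverSettings)
    sweep_factors: Sequence[float] = (0.35, 1.0, 10.0, 1e2, 1e3, 1e4, 1e5, 1e6, 1e7)
    mean_pressure: float = 100.0
    outlet_pressure: float = 0.0
    output_dir: str = "runs"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenarios"] = list(self.scenarios)
        d["sweep_factors"] = [float(f) for f in self.sweep_factors]
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "inflow" in d and isinstance(d["inflow"], dict):
            d["inflow"] = InflowSpec(**d["inflow"])
        if "solver" in d and isinstance(d["solver"], dict):
            d["solver"] = SolverSettings(**d["solver"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
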