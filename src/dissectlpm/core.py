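"""Domain types, unit conversions and circuit-element computation.

A dissected aortic segment is represented by an electrical analogy: each
lumen (true lumen TL, false lumen FL) is an L-type RLC compartment whose
elements follow from Poiseuille resistance, blood inertance and thin-wall
elastic compliance,

    R = 8 mu l / (pi r^4)        [Pa s m^-3]
    L = rho l / (pi r^2)         [Pa s^2 m^-3]
    C = 3 pi r^3 l / (2 E h)     [m^3 Pa^-1]

with ``r`` the inner radius, ``l`` the segment length, ``h`` the wall
thickness, ``mu``/``rho`` the fluid viscosity/density and ``E`` the wall
Young's modulus.  Intimal tears are pure resistances, the distal vascular
bed a pure resistance with a fixed outlet pressure.

Elements are computed in SI and exposed in clinical units
(mmHg, ml, s), which is also the unit system the simulator operates in.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from typing import Mapping, Optional

__all__ = [
    "PA_PER_MMHG",
    "ML_PER_M3",
    "InvalidGeometryError",
    "InvalidModelError",
    "LumenGeometry",
    "FluidProperties",
    "WallProperties",
    "LumpedElements",
    "TearSpec",
    "PeripheralBed",
    "DissectionModelSpec",
    "pressure_unit_convert",
    "convert_quantity",
    "lumen_resistance",
    "lumen_inertance",
    "lumen_compliance",
    "compute_elements",
    "young_modulus_from_compliance",
    "parse_scenario",
    "build_model",
]

PA_PER_MMHG = 133.322
ML_PER_M3 = 1.0e6

# clinical-per-SI multiplicative factors for each quantity kind
_CLINICAL_PER_SI = {
    "pressure": 1.0 / PA_PER_MMHG,                 # Pa -> mmHg
    "flow": ML_PER_M3,                             # m^3/s -> ml/s
    "volume": ML_PER_M3,                           # m^3 -> ml
    "resistance": 1.0 / (PA_PER_MMHG * ML_PER_M3),  # Pa s/m^3 -> mmHg s/ml
    "inertance": 1.0 / (PA_PER_MMHG * ML_PER_M3),   # Pa s^2/m^3 -> mmHg s^2/ml
    "compliance": PA_PER_MMHG * ML_PER_M3,          # m^3/Pa -> ml/mmHg
}


class InvalidGeometryError(ValueError):
    """Raised for non-physical geometry or fluid/wall parameters."""


class InvalidModelError(ValueError):
    """Raised for an ill-posed circuit specification."""


def convert_quantity(value: float, quantity: str, direction: str) -> float:
    """Convert ``value`` between SI and clinical units.

    Parameters
    ----------
    quantity
        One of ``pressure``, ``flow``, ``volume``, ``resistance``,
        ``inertance``, ``compliance``.
    direction
        ``"si_to_clinical"`` or ``"clinical_to_si"``.  Applying the two
        directions in sequence is the identity.
    """
    try:
        factor = _CLINICAL_PER_SI[quantity]
    except KeyError:
        raise ValueError(f"unknown quantity kind {quantity!r}") from None
    if direction == "si_to_clinical":
        return value * factor
    if direction == "clinical_to_si":
        return value / factor
    raise ValueError(f"unknown direction {direction!r}")


def pressure_unit_convert(value: float, direction: str) -> float:
    """Convert a pressure between Pa and mmHg (1 mmHg = 133.322 Pa).

    ``direction`` is ``"pa_to_mmhg"`` or ``"mmhg_to_pa"``.
    """
    if direction == "pa_to_mmhg":
        return value / PA_PER_MMHG
    if direction == "mmhg_to_pa":
        return value * PA_PER_MMHG
    raise ValueError(f"unknown direction {direction!r}")


def _require_positive(name: str, value: float) -> None:
    if not (value > 0.0) or not math.isfinite(value):
        raise InvalidGeometryError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class LumenGeometry:
    """Cylindrical lumen geometry (SI metres)."""

    inner_radius: float
    wall_thickness: float
    length: float

    def __post_init__(self) -> None:
        _require_positive("inner_radius", self.inner_radius)
        _require_positive("wall_thickness", self.wall_thickness)
        _require_positive("length", self.length)
        if self.wall_thickness >= self.inner_radius:
            raise InvalidGeometryError(
                "thin-wall assumption requires wall_thickness < inner_radius "
                f"(h={self.wall_thickness}, r={self.inner_radius})"
            )


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid dynamic viscosity (Pa s) and density (kg m^-3)."""

    dynamic_viscosity: float
    density: float

    def __post_init__(self) -> None:
        _require_positive("dynamic_viscosity", self.dynamic_viscosity)
        _require_positive("density", self.density)


#: water at 25 degC, the perfusion fluid of the bench circuit being emulated
WATER_25C = FluidProperties(dynamic_viscosity=8.9e-4, density=997.0479)


@dataclass(frozen=True)
class WallProperties:
    """Wall elasticity as a Young's modulus (Pa). Rigid walls are approached
    by a large finite modulus, never by literal zero compliance."""

    young_modulus: float

    def __post_init__(self) -> None:
        _require_positive("young_modulus", self.young_modulus)


@dataclass(frozen=True)
class LumpedElements:
    """RLC elements of one lumen in clinical units
    (mmHg s ml^-1, mmHg s^2 ml^-1, ml mmHg^-1)."""

    resistance: float
    inertance: float
    compliance: float

    def __post_init__(self) -> None:
        _require_positive("resistance", self.resistance)
        _require_positive("inertance", self.inertance)
        if self.compliance < 0.0 or not math.isfinite(self.compliance):
            raise InvalidModelError(f"compliance must be >= 0, got {self.compliance!r}")


@dataclass(frozen=True)
class TearSpec:
    """An intimal tear, modelled as a rigid orifice of pure resistance.

    ``diameter`` (m) is carried for tear-velocity computation; ``resistance``
    (mmHg s ml^-1) is a fitted configuration constant, not derived from the
    diameter."""

    resistance: float
    diameter: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive("resistance", self.resistance)
        if self.diameter is not None:
            _require_positive("diameter", self.diameter)


@dataclass(frozen=True)
class PeripheralBed:
    """Distal vascular bed: pure resistance draining to a fixed outlet
    pressure (default venous zero)."""

    resistance: float
    outlet_pressure: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("resistance", self.resistance)
        if not math.isfinite(self.outlet_pressure):
            raise InvalidModelError("outlet_pressure must be finite")


@dataclass(frozen=True)
class DissectionModelSpec:
    """The complete dissection circuit.

    Tears may be absent (``None``); an absent tear is removed structurally,
    its branch carries identically zero flow.  At least one tear must be
    present, otherwise the false lumen is unreachable and the system
    degenerates to a single vessel.
    """

    scenario_id: str
    tl_elements: LumpedElements
    fl_elements: LumpedElements
    proximal_tear: Optional[TearSpec]
    distal_tear: Optional[TearSpec]
    peripheral: PeripheralBed

    def __post_init__(self) -> None:
        if self.proximal_tear is None and self.distal_tear is None:
            raise InvalidModelError(
                f"scenario {self.scenario_id!r}: at least one tear must be present"
            )
        if self.tl_elements.compliance <= 0.0 or self.fl_elements.compliance <= 0.0:
            raise InvalidModelError(
                "lumen compliances must be strictly positive inside the circuit; "
                "request rigid walls through an elasticity factor instead"
            )

    @property
    def has_proximal_tear(self) -> bool:
        return self.proximal_tear is not None

    @property
    def has_distal_tear(self) -> bool:
        return self.distal_tear is not None

    def with_elasticity_factor(self, factor: float) -> "DissectionModelSpec":
        """Scale both walls' Young's moduli by ``factor``.

        Compliance is inversely proportional to the modulus, so both lumen
        compliances are divided by ``factor``; R and L are unaffected.
        """
        if not (factor > 0.0) or not math.isfinite(factor):
            raise InvalidModelError(f"elasticity factor must be positive finite, got {factor!r}")
        return replace(
            self,
            tl_elements=replace(self.tl_elements, compliance=self.tl_elements.compliance / factor),
            fl_elements=replace(self.fl_elements, compliance=self.fl_elements.compliance / factor),
        )


# --------------------------------------------------------------------------
# element formulas


def lumen_resistance(geometry: LumenGeometry, fluid: FluidProperties) -> float:
    """Poiseuille resistance 8*mu*l/(pi r^4), returned in mmHg s ml^-1."""
    r_si = 8.0 * fluid.dynamic_viscosity * geometry.length / (math.pi * geometry.inner_radius**4)
    return convert_quantity(r_si, "resistance", "si_to_clinical")


def lumen_inertance(geometry: LumenGeometry, fluid: FluidProperties) -> float:
    """Blood inertance rho*l/(pi r^2), returned in mmHg s^2 ml^-1."""
    l_si = fluid.density * geometry.length / (math.pi * geometry.inner_radius**2)
    return convert_quantity(l_si, "inertance", "si_to_clinical")


def lumen_compliance(geometry: LumenGeometry, wall: WallProperties) -> float:
    """Thin-wall elastic compliance 3*pi*r^3*l/(2*E*h), in ml mmHg^-1."""
    c_si = (
        3.0 * math.pi * geometry.inner_radius**3 * geometry.length
        / (2.0 * wall.young_modulus * geometry.wall_thickness)
    )
    return convert_quantity(c_si, "compliance", "si_to_clinical")


def compute_elements(
    geometry: LumenGeometry, fluid: FluidProperties, wall: WallProperties
) -> LumpedElements:
    """Assemble the full RLC element set of one lumen."""
    return LumpedElements(
        resistance=lumen_resistance(geometry, fluid),
        inertance=lumen_inertance(geometry, fluid),
        compliance=lumen_compliance(geometry, wall),
    )


def young_modulus_from_compliance(geometry: LumenGeometry, compliance: float) -> float:
    """Invert the compliance formula: the Young's modulus (Pa) that yields
    ``compliance`` (ml mmHg^-1) for this geometry.

    Raises for non-positive compliance (a rigid wall has no finite modulus).
    """
    if not (compliance > 0.0) or not math.isfinite(compliance):
        raise InvalidModelError(
            f"no finite Young's modulus for compliance {compliance!r}; "
            "zero compliance means a rigid wall"
        )
    c_si = convert_quantity(compliance, "compliance", "clinical_to_si")
    return (
        3.0 * math.pi * geometry.inner_radius**3 * geometry.length
        / (2.0 * c_si * geometry.wall_thickness)
    )


# --------------------------------------------------------------------------
# scenario assembly

_SCENARIO_RE = re.compile(r"^S_?(\d+),(\d+)$")
_TEAR_SIZE_CLASS = {4: "small", 10: "large"}


def parse_scenario(label: str) -> tuple[int, int]:
    """Parse a scenario label ``S_p,d`` into (proximal, distal) tear
    diameters in mm; each is one of 0 (absent), 4 (small) or 10 (large)."""
    m = _SCENARIO_RE.match(label.strip())
    if not m:
        raise InvalidModelError(f"unrecognised scenario label {label!r} (expected e.g. 'S_4,10')")
    p, d = int(m.group(1)), int(m.group(2))
    for size in (p, d):
        if size not in (0, 4, 10):
            raise InvalidModelError(f"tear diameter must be 0, 4 or 10 mm, got {size} in {label!r}")
    if p == 0 and d == 0:
        raise InvalidModelError("scenario S_0,0 has no tear: the false lumen would be unreachable")
    return p, d


def _make_tear(size_mm: int, tear_resistances: Mapping[str, float]) -> Optional[TearSpec]:
    if size_mm == 0:
        return None
    klass = _TEAR_SIZE_CLASS[size_mm]
    try:
        resistance = tear_resistances[klass]
    except KeyError:
        raise InvalidModelError(f"tear resistance table lacks entry {klass!r}") from None
    return TearSpec(resistance=resistance, diameter=size_mm * 1e-3)


def build_model(
    scenario: str,
    tl_geometry: LumenGeometry,
    fl_geometry: LumenGeometry,
    tl_wall: WallProperties,
    fl_wall: WallProperties,
    tear_resistances: Mapping[str, float],
    peripheral: PeripheralBed,
    fluid: FluidProperties = WATER_25C,
    tl_compliance: Optional[float] = None,
    fl_compliance: Optional[float] = None,
) -> DissectionModelSpec:
    """Build the dissection circuit for a scenario label ``S_p,d``.

    R and L of each lumen are computed from geometry and fluid; compliances
    from the wall moduli unless ``tl_compliance``/``fl_compliance`` override
    them with directly fitted values (clinical units).  Tear resistances come
    from the ``{"small": ..., "large": ...}`` configuration table, absent
    tears (size 0) are removed from the circuit.
    """
    p, d = parse_scenario(scenario)
    tl = compute_elements(tl_geometry, fluid, tl_wall)
    fl = compute_elements(fl_geometry, fluid, fl_wall)
    if tl_compliance is not None:
        tl = replace(tl, compliance=tl_compliance)
    if fl_compliance is not None:
        fl = replace(fl, compliance=fl_compliance)
    return DissectionModelSpec(
        scenario_id=f"S_{p},{d}",
        tl_elements=tl,
        fl_elements=fl,
        proximal_tear=_make_tear(p, tear_resistances),
        distal_tear=_make_tear(d, tear_resistances),
        peripheral=peripheral,
    )
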