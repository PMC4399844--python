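"""Circuit-element formulas, unit conversions and model assembly."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dissectlpm.core import (
    DissectionModelSpec,
    FluidProperties,
    InvalidGeometryError,
    InvalidModelError,
    LumenGeometry,
    LumpedElements,
    PeripheralBed,
    TearSpec,
    WATER_25C,
    WallProperties,
    build_model,
    convert_quantity,
    lumen_compliance,
    lumen_inertance,
    lumen_resistance,
    parse_scenario,
    pressure_unit_convert,
    young_modulus_from_compliance,
)
from dissectlpm.scenarios import (
    FL_COMPLIANCES,
    FL_GEOMETRY,
    FL_YOUNG_MODULI_PA,
    TEAR_RESISTANCES,
    TL_GEOMETRY,
)

MMHG = 133.322


class TestUnitConversion:
    def test_definition_values(self):
        assert pressure_unit_convert(133.322, "pa_to_mmhg") == pytest.approx(1.0)
        assert pressure_unit_convert(1.0, "mmhg_to_pa") == pytest.approx(133.322)
        assert convert_quantity(1.0, "compliance", "si_to_clinical") == pytest.approx(1.33322e8)
        assert pressure_unit_convert(0.0, "pa_to_mmhg") == 0.0

    @given(st.floats(-1e6, 1e6, allow_nan=False))
    def test_round_trip_identity(self, x):
        for q in ("pressure", "flow", "resistance", "inertance", "compliance"):
            back = convert_quantity(convert_quantity(x, q, "si_to_clinical"), q, "clinical_to_si")
            assert back == pytest.approx(x, rel=1e-12, abs=1e-300)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            pressure_unit_convert(1.0, "sideways")


class TestElementFormulas:
    """Hand-evaluated Poiseuille / inertance / thin-wall compliance values."""

    def test_tl_resistance(self):
        r = lumen_resistance(TL_GEOMETRY, WATER_25C)
        assert r * MMHG * 1e6 == pytest.approx(8.853e4, rel=1e-3)  # SI check
        assert r == pytest.approx(6.641e-4, rel=1e-3)

    def test_fl_resistance(self):
        r = lumen_resistance(FL_GEOMETRY, WATER_25C)
        assert r * MMHG * 1e6 == pytest.approx(5.330e3, rel=1e-3)
        assert r == pytest.approx(3.998e-5, rel=1e-3)

    def test_tl_inertance(self):
        l = lumen_inertance(TL_GEOMETRY, WATER_25C)
        assert l * MMHG * 1e6 == pytest.approx(7.934e5, rel=1e-3)
        assert l == pytest.approx(5.951e-3, rel=1e-3)

    def test_fl_inertance(self):
        assert lumen_inertance(FL_GEOMETRY, WATER_25C) * MMHG * 1e6 == pytest.approx(
            1.947e5, rel=1e-3
        )

    @given(st.floats(1e-3, 0.1), st.floats(0.01, 1.0))
    def test_resistance_r4_scaling(self, r, length):
        geom = LumenGeometry(r, r / 10, length)
        geom2 = LumenGeometry(2 * r, r / 10, length)
        assert lumen_resistance(geom, WATER_25C) == pytest.approx(
            16 * lumen_resistance(geom2, WATER_25C), rel=1e-12
        )

    @given(st.floats(1e-3, 0.1), st.floats(0.01, 1.0))
    def test_inertance_linear_in_length(self, r, length):
        geom = LumenGeometry(r, r / 10, length)
        half = LumenGeometry(r, r / 10, length / 2)
        assert lumen_inertance(half, WATER_25C) == pytest.approx(
            lumen_inertance(geom, WATER_25C) / 2, rel=1e-12
        )

    @given(st.floats(1e-3, 0.05, allow_nan=False))
    def test_element_monotonicity_in_radius(self, r):
        wall = WallProperties(1e6)
        a = LumenGeometry(r, r / 20, 0.16)
        b = LumenGeometry(1.5 * r, r / 20, 0.16)
        assert lumen_resistance(b, WATER_25C) < lumen_resistance(a, WATER_25C)
        assert lumen_inertance(b, WATER_25C) < lumen_inertance(a, WATER_25C)
        assert lumen_compliance(b, wall) > lumen_compliance(a, wall)

    def test_compliance_inverse_modulus_scaling(self):
        c1 = lumen_compliance(FL_GEOMETRY, WallProperties(1e6))
        c10 = lumen_compliance(FL_GEOMETRY, WallProperties(1e7))
        assert c1 == pytest.approx(10 * c10, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidGeometryError):
            LumenGeometry(-0.01, 0.001, 0.16)
        with pytest.raises(InvalidGeometryError):
            LumenGeometry(0.01, 0.02, 0.16)  # thick wall breaks thin-wall assumption
        with pytest.raises(InvalidGeometryError):
            WallProperties(0.0)
        with pytest.raises(InvalidGeometryError):
            FluidProperties(-1.0, 1000.0)


class TestCalibratedComplianceConsistency:
    """The catalogued FL wall moduli and compliances are mutually consistent
    under the thin-wall formula for every scenario (within print rounding)."""

    @pytest.mark.parametrize("label", sorted(FL_COMPLIANCES))
    def test_fl_modulus_compliance_pair(self, label):
        c = lumen_compliance(FL_GEOMETRY, WallProperties(FL_YOUNG_MODULI_PA[label]))
        assert c == pytest.approx(FL_COMPLIANCES[label], rel=5e-3)

    def test_anchor_values(self):
        assert lumen_compliance(FL_GEOMETRY, WallProperties(1.55e6)) == pytest.approx(
            0.2732, rel=1e-3
        )
        assert lumen_compliance(FL_GEOMETRY, WallProperties(2.49e6)) == pytest.approx(
            0.1700, rel=1e-3
        )


class TestModulusInversion:
    @pytest.mark.parametrize(
        "compliance,expected_mpa", [(0.1110, 3.82), (0.1427, 2.97)]
    )
    def test_table_pairs(self, compliance, expected_mpa):
        e = young_modulus_from_compliance(FL_GEOMETRY, compliance)
        assert e / 1e6 == pytest.approx(expected_mpa, rel=5e-3)

    @given(st.floats(1e4, 1e9))
    def test_round_trip(self, e):
        c = lumen_compliance(FL_GEOMETRY, WallProperties(e))
        assert young_modulus_from_compliance(FL_GEOMETRY, c) == pytest.approx(e, rel=1e-12)

    def test_rigid_wall_has_no_modulus(self):
        with pytest.raises(InvalidModelError):
            young_modulus_from_compliance(FL_GEOMETRY, 0.0)


class TestBuildModel:
    def _build(self, label):
        return build_model(
            label,
            TL_GEOMETRY,
            FL_GEOMETRY,
            WallProperties(1.07e6),
            WallProperties(4.19e6),
            TEAR_RESISTANCES,
            PeripheralBed(1.5),
        )

    def test_two_tear_scenario(self):
        m = self._build("S_4,4")
        assert m.has_proximal_tear and m.has_distal_tear
        assert m.proximal_tear.resistance == pytest.approx(2.2200)
        assert m.distal_tear.resistance == pytest.approx(2.2200)
        assert m.proximal_tear.diameter == pytest.approx(0.004)

    def test_single_tear_scenario(self):
        m = self._build("S_10,0")
        assert m.distal_tear is None
        assert m.proximal_tear.resistance == pytest.approx(0.1434)

    @pytest.mark.parametrize("label", ["S_0,0", "S_5,4", "banana", "S_4"])
    def test_bad_labels_rejected(self, label):
        with pytest.raises(InvalidModelError):
            parse_scenario(label)

    def test_elasticity_factor_scales_compliance_only(self):
        m = self._build("S_4,4")
        m2 = m.with_elasticity_factor(10.0)
        assert m2.tl_elements.compliance == pytest.approx(m.tl_elements.compliance / 10)
        assert m2.fl_elements.compliance == pytest.approx(m.fl_elements.compliance / 10)
        assert m2.tl_elements.resistance == m.tl_elements.resistance
        assert m2.fl_elements.inertance == m.fl_elements.inertance

    def test_tearless_circuit_rejected(self):
        el = LumpedElements(1e-3, 1e-3, 0.1)
        with pytest.raises(InvalidModelError):
            DissectionModelSpec("S_x", el, el, None, None, PeripheralBed(1.0))

    def test_tear_resistance_positive(self):
        with pytest.raises(InvalidGeometryError):
            TearSpec(resistance=-1.0)
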