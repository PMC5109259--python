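"""Hazard-quotient route models against closed-form hand calculations."""

import numpy as np
import pytest

from rpra.exposure import (
    ExposureContext,
    MetalProperties,
    conc_groundwater,
    hq_dermal_solid,
    hq_dermal_water,
    hq_ingestion,
    hq_inhalation,
    hq_vegetable,
)


class TestIngestion:
    def test_zero_concentration_gives_zero(self, point_ctx, simple_props):
        assert hq_ingestion(0.0, point_ctx, simple_props, "soil") == 0.0

    def test_soil_hand_calculation(self, simple_props):
        # 100 mg/kg * 100 mg/d * 350 d/yr * 24 yr * 1e-6 / (60 * 8760 * 3e-4)
        ctx = ExposureContext(ed=24, bw=60, at=8760, ir_s=100, ef_oa=350)
        hq = hq_ingestion(100.0, ctx, simple_props, "soil")
        expected = 100 * 100 * 350 * 24 * 1e-6 / (60 * 8760 * 3e-4)
        assert hq == pytest.approx(expected, rel=1e-12)
        assert hq == pytest.approx(0.533, abs=5e-4)

    def test_water_unit_factor(self, point_ctx, simple_props):
        # waters use 1e-3 with conc in ug/L and IR_w in L/d
        hq = hq_ingestion(3.2, point_ctx, simple_props, "surface_water")
        expected = 3.2 * 2.0 * 350 * 24 * 1e-3 / (60 * 8760 * 3e-4)
        assert hq == pytest.approx(expected, rel=1e-12)

    def test_doubling_rfd_halves_hq(self, point_ctx, simple_props):
        hq1 = hq_ingestion(50.0, point_ctx, simple_props, "soil")
        doubled = MetalProperties(
            metal="As", rfd_oral=6e-4, rfd_dermal=1e-4, rfd_inhalation=8.57e-5,
            kd=250, puf=0.1, kp=1e-3, abs_f=0.03,
        )
        assert hq_ingestion(50.0, point_ctx, doubled, "soil") == pytest.approx(hq1 / 2)

    def test_unknown_medium_rejected(self, point_ctx, simple_props):
        with pytest.raises(ValueError, match="medium"):
            hq_ingestion(1.0, point_ctx, simple_props, "air")

    def test_vectorized_over_iterations(self, point_ctx, simple_props):
        conc = np.array([0.0, 10.0, 20.0])
        hq = hq_ingestion(conc, point_ctx, simple_props, "soil")
        assert hq.shape == (3,)
        assert hq[2] == pytest.approx(2 * hq[1], rel=1e-12)


class TestGroundwaterLeaching:
    def test_hand_calculation(self):
        # 1000 * 50 / ((25 + 0.3/1.5) * 20) = 99.2 ug/L
        c = conc_groundwater(50.0, 25.0, 0.3, 1.5, 20.0)
        assert c == pytest.approx(1000 * 50 / ((25 + 0.2) * 20), rel=1e-12)
        assert c == pytest.approx(99.2, abs=0.01)

    def test_strong_sorption_limit(self):
        assert conc_groundwater(50.0, 1e12, 0.3, 1.5, 20.0) < 1e-7

    def test_pure_pore_water_bookkeeping(self):
        # df=1, kd=0, theta_w/rho_b=1 -> C_gw = 1000 * c_ts
        assert conc_groundwater(2.0, 0.0, 1.0, 1.0, 1.0) == pytest.approx(2000.0)

    def test_monotonicity(self):
        base = conc_groundwater(50.0, 25.0, 0.3, 1.5, 20.0)
        assert conc_groundwater(60.0, 25.0, 0.3, 1.5, 20.0) > base
        assert conc_groundwater(50.0, 30.0, 0.3, 1.5, 20.0) < base
        assert conc_groundwater(50.0, 25.0, 0.3, 1.5, 30.0) < base

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            conc_groundwater(50.0, 0.0, 0.3, 1.5, 0.0)


class TestVegetable:
    def test_zero_uptake_gives_zero(self, point_ctx, simple_props):
        assert hq_vegetable(2.0, point_ctx, simple_props, puf=0.0) == 0.0

    def test_hand_calculation(self, simple_props):
        # 2 * 0.1 * 0.3 * (1-0.9) * 350 * 24 / (60 * 8760 * 1e-3)
        props = MetalProperties(
            metal="Cd", rfd_oral=1e-3, rfd_dermal=1e-4, rfd_inhalation=1e-3,
            kd=250, puf=0.1, kp=1e-3, abs_f=0.001,
        )
        ctx = ExposureContext(ed=24, bw=60, at=8760, ir_v=0.3, theta_v=0.9, ef_ia=350)
        hq = hq_vegetable(2.0, ctx, props)
        expected = 2 * 0.1 * 0.3 * 0.1 * 350 * 24 / (60 * 8760 * 1e-3)
        assert hq == pytest.approx(expected, rel=1e-12)
        assert hq == pytest.approx(0.0959, abs=1e-4)

    def test_linear_in_concentration(self, point_ctx, simple_props):
        assert hq_vegetable(4.0, point_ctx, simple_props) == pytest.approx(
            2 * hq_vegetable(2.0, point_ctx, simple_props), rel=1e-12
        )

    def test_water_content_above_one_rejected(self, simple_props):
        ctx = ExposureContext(ed=24, bw=60, ir_v=0.3, theta_v=1.0, ef_ia=350)
        with pytest.raises(ValueError, match="theta_v"):
            hq_vegetable(2.0, ctx, simple_props)


class TestDermalSolid:
    def test_zero_absorption_gives_zero(self, point_ctx):
        props = MetalProperties(
            metal="Zn", rfd_oral=0.3, rfd_dermal=0.3, rfd_inhalation=0.3,
            kd=700, puf=0.1, kp=6e-4, abs_f=0.0,
        )
        assert hq_dermal_solid(100.0, point_ctx, props, "soil") == 0.0

    def test_hand_calculation_with_area_conversion(self, simple_props):
        # 0.5 m^2 = 5000 cm^2:
        # 100 * 5000 * 0.2 * 0.03 * 225 * 24 * 1e-6 / (60 * 8760 * 1e-4)
        ctx = ExposureContext(ed=24, bw=60, at=8760, sa_o=0.5, af_sa=0.2, ef_oa=225)
        hq = hq_dermal_solid(100.0, ctx, simple_props, "soil")
        expected = 100 * 5000 * 0.2 * 0.03 * 225 * 24 * 1e-6 / (60 * 8760 * 1e-4)
        assert hq == pytest.approx(expected, rel=1e-12)
        assert hq == pytest.approx(0.308, abs=5e-4)

    def test_sediment_binds_swimming_parameters(self, point_ctx, simple_props):
        hq = hq_dermal_solid(100.0, point_ctx, simple_props, "sediment")
        expected = 100 * 1.8e4 * 0.5 * 0.03 * 30 * 24 * 1e-6 / (60 * 8760 * 1e-4)
        assert hq == pytest.approx(expected, rel=1e-12)


class TestDermalWater:
    def test_zero_permeability_gives_zero(self, point_ctx):
        props = MetalProperties(
            metal="Pb", rfd_oral=3.5e-3, rfd_dermal=3.5e-3, rfd_inhalation=3.5e-3,
            kd=2800, puf=0.01, kp=0.0, abs_f=0.001,
        )
        with pytest.raises(ValueError, match="kp"):
            hq_dermal_water(10.0, point_ctx, props)

    def test_absorbed_dose_hand_calculation(self, simple_props):
        # 10 ug/L = 1e-5 mg/cm^3; dose = 1e-5*1e-3*18000*1*30*24/(60*8760)
        ctx = ExposureContext(
            ed=24, bw=60, at=8760, sa_sw=1.8, et_sw=1.0, ef_sw=30
        )
        hq = hq_dermal_water(10.0, ctx, simple_props)
        dose = 10 * 1e-6 * 1e-3 * 1.8e4 * 1.0 * 30 * 24 / (60 * 8760)
        assert dose == pytest.approx(2.466e-7, abs=2e-10)
        assert hq == pytest.approx(dose / simple_props.rfd_dermal, rel=1e-12)

    def test_linear_in_event_time(self, point_ctx, simple_props):
        hq1 = hq_dermal_water(10.0, point_ctx, simple_props)
        ctx2 = ExposureContext(
            ed=24, bw=60, at=8760, sa_sw=1.8, et_sw=2.0, ef_sw=30
        )
        assert hq_dermal_water(10.0, ctx2, simple_props) == pytest.approx(
            2 * hq1, rel=1e-12
        )


class TestInhalation:
    def test_huge_pef_drives_hq_to_zero(self, point_ctx, simple_props):
        ctx = ExposureContext(ed=24, bw=60, ir_a=15, ef_oa=225, pef=1e30)
        assert hq_inhalation(1.0, ctx, simple_props) < 1e-20

    def test_volatilization_dominates_for_mercury(self, point_ctx):
        hg = MetalProperties(
            metal="Hg", rfd_oral=3e-4, rfd_dermal=2.1e-5, rfd_inhalation=8.57e-5,
            kd=2000, puf=0.006, kp=1e-3, abs_f=0.001, vf=32376.4,
        )
        hq = hq_inhalation(0.4, point_ctx, hg)
        # vapour term 1/VF exceeds the dust term 1/PEF by ~4e4
        no_vf = MetalProperties(
            metal="Hg", rfd_oral=3e-4, rfd_dermal=2.1e-5, rfd_inhalation=8.57e-5,
            kd=2000, puf=0.006, kp=1e-3, abs_f=0.001, vf=None,
        )
        hq_dust = hq_inhalation(0.4, point_ctx, no_vf)
        assert hq_dust / hq < 1e-4
        expected = 0.4 * 15 * 225 * 24 * (1 / 1.36e9 + 1 / 32376.4) / (60 * 8760 * 8.57e-5)
        assert hq == pytest.approx(expected, rel=1e-12)


class TestExposureContext:
    def test_at_defaults_to_ed_times_365(self):
        ctx = ExposureContext(ed=24, bw=60)
        assert np.asarray(ctx.at) == pytest.approx(8760.0)

    def test_at_below_noncarcinogenic_convention_rejected(self):
        with pytest.raises(ValueError, match="at"):
            ExposureContext(ed=24, bw=60, at=5000)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError, match="bw"):
            ExposureContext(ed=24, bw=0.0)

    def test_missing_binding_named_in_error(self, simple_props):
        ctx = ExposureContext(ed=24, bw=60)
        with pytest.raises(ValueError, match="ir_s"):
            hq_ingestion(1.0, ctx, simple_props, "soil")
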