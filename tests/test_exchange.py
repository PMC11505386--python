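"""Carrier chemistry, AL gas exchange and reservoir balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecco2rsim.exchange import (CarrierChemistry, ConditioningConfig, Fluid,
                                LiquidState, LungConfig, ReservoirState,
                                al_exchange, conditioning_inlet_pco2,
                                conditioning_pass, content_curve,
                                egco2_of_sweep, removal_rate, reservoir_step,
                                short_lung, tall_lung, R_MMHG_L)

CHEM = CarrierChemistry()


class TestContentCurve:
    def test_zero_pco2_gives_zero_content(self):
        assert content_curve(Fluid.water, 0.0) == 0.0

    def test_water_is_henrys_law(self):
        # alpha_w * pCO2 = 0.03 * 40
        assert content_curve(Fluid.water, 40.0) == pytest.approx(1.20)

    def test_blood_carries_more_than_water(self):
        # bicarbonate/carbamino storage dominates physical solubility
        for p in np.linspace(10.0, 100.0, 19):
            assert content_curve(Fluid.blood, p) > content_curve(
                Fluid.water, p)

    def test_negative_pco2_rejected(self):
        with pytest.raises(ValueError):
            content_curve(Fluid.water, -1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.001, 200.0),
           st.sampled_from([Fluid.water, Fluid.blood]))
    def test_curve_invertible(self, pco2, fluid):
        c = CHEM.content(fluid, pco2)
        assert CHEM.pco2(fluid, c) == pytest.approx(pco2, rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.0, 200.0), st.floats(0.0, 200.0),
           st.sampled_from([Fluid.water, Fluid.blood]))
    def test_curve_strictly_increasing(self, p1, p2, fluid):
        lo, hi = sorted((p1, p2))
        if hi - lo > 1e-9:
            assert CHEM.content(fluid, lo) < CHEM.content(fluid, hi)


class TestEgco2OfSweep:
    def test_low_sweep_reaches_equilibration_limit(self):
        lung = tall_lung(beta=2.0)
        assert egco2_of_sweep(40.0, 1e-9, lung) == pytest.approx(
            40.0, rel=1e-6)
        assert egco2_of_sweep(40.0, 0.0, lung) == 40.0

    def test_transfer_unit_closed_form(self):
        lung = tall_lung(beta=2.0)
        expected = 40.0 * (1.0 - math.exp(-1.0))   # 25.285 mmHg
        assert egco2_of_sweep(40.0, 2.0, lung) == pytest.approx(expected)
        assert egco2_of_sweep(40.0, 2.0, lung) == pytest.approx(25.285, abs=5e-3)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.0, 150.0), st.floats(0.01, 10.0))
    def test_never_exceeds_liquid_inlet(self, pl, sweep):
        # the device removes CO2; it cannot add it
        assert egco2_of_sweep(pl, sweep, tall_lung()) <= pl + 1e-12

    def test_strictly_decreasing_in_sweep(self):
        lung = tall_lung()
        sweeps = np.linspace(0.05, 7.0, 80)
        vals = [egco2_of_sweep(40.0, q, lung) for q in sweeps]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestRemovalRate:
    def test_zero_egco2_removes_nothing(self):
        assert removal_rate(0.0, 3.0) == 0.0

    def test_ideal_gas_arithmetic(self):
        # independent route: atm-based ideal gas law
        v_co2 = 2.0 * 25.285 / 760.0          # L/min of pure CO2
        expected = (760.0 / 760.0) * v_co2 / (0.0820574 * 310.0) * 1000.0
        got = removal_rate(25.285, 2.0, 760.0, 310.0)
        assert got == pytest.approx(expected, rel=1e-4)
        assert got == pytest.approx(2.62, abs=0.01)

    def test_composed_removal_increasing_in_sweep(self):
        lung = tall_lung(beta=2.0)
        sweeps = np.linspace(0.1, 7.0, 60)
        rates = [removal_rate(egco2_of_sweep(40.0, q, lung), q)
                 for q in sweeps]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_bad_temperature_rejected(self):
        with pytest.raises(ValueError):
            removal_rate(20.0, 1.0, 760.0, 0.0)


class TestConditioning:
    def test_mole_fraction_mixing(self):
        assert conditioning_inlet_pco2(
            ConditioningConfig(air_flow=2.0, co2_flow=0.1)
        ) == pytest.approx(760.0 * 0.1 / 2.1)      # 36.19 mmHg
        assert conditioning_inlet_pco2(
            ConditioningConfig(air_flow=2.0, co2_flow=0.8)
        ) == pytest.approx(760.0 * 0.8 / 2.8)      # 217.14 mmHg
        assert conditioning_inlet_pco2(
            ConditioningConfig(air_flow=2.0, co2_flow=0.0)) == 0.0

    def test_pass_relaxes_toward_gas(self):
        liq = LiquidState.from_pco2(1.0, 20.0)
        cfg = ConditioningConfig(air_flow=2.0, co2_flow=0.1, efficiency=0.8)
        out = conditioning_pass(liq, cfg)
        gas = 760.0 * 0.1 / 2.1
        assert out.pco2 == pytest.approx(20.0 + 0.8 * (gas - 20.0))
        assert out.content == pytest.approx(CHEM.content(Fluid.water,
                                                         out.pco2))

    def test_full_efficiency_equilibrates(self):
        liq = LiquidState.from_pco2(1.0, 20.0)
        cfg = ConditioningConfig(air_flow=2.0, co2_flow=0.1, efficiency=1.0)
        assert conditioning_pass(liq, cfg).pco2 == pytest.approx(
            760.0 * 0.1 / 2.1)

    def test_loader_only_adds(self):
        # gas leaner than liquid: no stripping
        liq = LiquidState.from_pco2(1.0, 50.0)
        cfg = ConditioningConfig(air_flow=2.0, co2_flow=0.1, efficiency=0.8)
        assert conditioning_pass(liq, cfg).pco2 == 50.0


class TestAlExchange:
    def test_removal_capped_by_liquid_supply(self):
        # tiny liquid flow: the gas cannot carry out more CO2 than arrives
        liq = LiquidState.from_pco2(0.01, 40.0)
        egco2, removal, out = al_exchange(liq, 5.0, tall_lung())
        assert removal <= liq.flow * liq.content + 1e-12
        assert out.content >= 0.0
        # effective EGCO2 back-computed from the capped removal
        assert egco2 == pytest.approx(
            removal * R_MMHG_L * 310.0 / (1000.0 * 5.0))

    def test_mass_consistent_per_pass(self):
        liq = LiquidState.from_pco2(1.0, 40.0)
        egco2, removal, out = al_exchange(liq, 2.0, tall_lung())
        assert liq.flow * (liq.content - out.content) == pytest.approx(
            removal)


class TestReservoir:
    def test_equilibrium_unchanged(self):
        res = ReservoirState.from_pco2(20.0)
        ret = LiquidState.from_content(1.0, res.content)
        out = reservoir_step(res, ret, dt=1.0)
        assert out.content == pytest.approx(res.content)

    def test_constant_influx_ramp_rate(self):
        # net influx 2.62 mmol/min into 18.93 L of water:
        # dpCO2/dt = 2.62/(V*alpha) = 4.613 mmHg/min
        res = ReservoirState.from_pco2(20.0)
        influx = 2.62   # mmol/min
        for _ in range(600):          # one minute at dt = 0.1 s
            ret = LiquidState.from_content(1.0, res.content + influx / 1.0)
            res = reservoir_step(res, ret, dt=0.1)
        assert res.pco2 - 20.0 == pytest.approx(2.62 / (18.93 * 0.03),
                                                rel=1e-6)


class TestLungVariants:
    def test_short_lung_has_half_resistance(self):
        assert short_lung().gas_resistance == pytest.approx(
            tall_lung().gas_resistance / 2.0)

    def test_invalid_lung_rejected(self):
        with pytest.raises(ValueError):
            LungConfig(beta=0.0)
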