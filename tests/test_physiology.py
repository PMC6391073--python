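"""Physiology calculus: growth rates, gas exchange, morphology, nutrients."""

import math

import numpy as np
import pytest

from cyanoecon import (BalanceTrace, GasExchangeRecord, ODTrace,
                       SyntheticSpec, doubling_time, gas_exchange_rates,
                       growth_rate_from_balance, growth_rate_from_od,
                       nutrient_balance, per_cell_to_per_gdw,
                       per_gdw_to_per_cell, photosynthesis_ratios,
                       simulate_gas_trace, simulate_turbidostat,
                       sphere_volume)
from cyanoecon.physiology import flow_rate_from_readings


class TestGrowthRateFromOD:
    def test_direct_formula_on_turbidostat_band(self):
        trace = ODTrace(time=[0.0, 1.0], od680=[0.60, 0.66])
        mean, sd, table = growth_rate_from_od(trace)
        assert mean == pytest.approx(math.log(0.66 / 0.60), abs=1e-12)
        assert mean == pytest.approx(0.0953, abs=1e-4)

    def test_constant_od_gives_zero(self):
        trace = ODTrace(time=np.linspace(0, 5, 20), od680=np.full(20, 0.62))
        mean, sd, _ = growth_rate_from_od(trace)
        assert mean == 0.0

    def test_sawtooth_round_trip_is_exact(self):
        spec = SyntheticSpec(seed=3)
        trace = simulate_turbidostat(0.05, spec, duration=48.0)
        assert len(trace.dilution_events) >= 20
        mean, sd, table = growth_rate_from_od(trace)
        assert mean == pytest.approx(0.05, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_window_spanning_dilution_without_segments_errors(self):
        # two samples bracketing a dilution: no usable segment inside
        trace = ODTrace(time=[0.0, 1.0], od680=[0.66, 0.60])
        with pytest.raises(ValueError):
            growth_rate_from_od(trace)

    def test_invalid_traces_rejected(self):
        with pytest.raises(ValueError):
            ODTrace(time=[0.0, 1.0], od680=[0.6, -0.1])
        with pytest.raises(ValueError):
            ODTrace(time=[1.0, 0.5], od680=[0.6, 0.62])


class TestDoublingTime:
    @pytest.mark.parametrize("mu, expected", [
        (0.025, 27.7),   # slowest measured growth
        (0.093, 7.5),    # photoinhibited growth
    ])
    def test_reported_doubling_times(self, mu, expected):
        assert round(doubling_time(mu), 1) == expected

    def test_identity(self):
        assert doubling_time(math.log(2.0)) == pytest.approx(1.0)
        # TD and mu are mutual inverses through ln 2
        assert doubling_time(doubling_time(3.5)) == pytest.approx(3.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)


class TestBalanceGrowthRate:
    def test_direct_ratio(self):
        assert growth_rate_from_balance(BalanceTrace(f=40.0, V=400.0)) == 0.1
        assert growth_rate_from_balance(BalanceTrace(f=0.0, V=400.0)) == 0.0

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            BalanceTrace(f=1.0, V=0.0)

    def test_flow_recovered_from_noisy_readings(self, rng):
        t = np.linspace(0.0, 24.0, 49)
        mass = 2000.0 - 40.0 * t + rng.normal(0.0, 5.0, t.size)
        f_hat, se = flow_rate_from_readings(t, mass)
        assert abs(f_hat - 40.0) < 2.0 * se + 1e-9


class TestGasExchange:
    def test_planted_slopes_recovered(self):
        spec = SyntheticSpec(seed=4)
        t, y, phases = simulate_gas_trace(1.61, 0.35, spec)
        rec = gas_exchange_rates(t, y, phases, co2_efflux_deficit=0.78)
        assert rec.NP == pytest.approx(1.61, rel=1e-9)
        assert rec.R_dark == pytest.approx(0.35, rel=1e-9)
        assert rec.GP == pytest.approx(1.96, rel=1e-9)

    def test_zero_slopes_give_zero_rates(self):
        t, y, phases = simulate_gas_trace(0.0, 0.0, SyntheticSpec(seed=5))
        rec = gas_exchange_rates(t, y, phases)
        assert rec.NP == 0.0 and rec.R_dark == 0.0 and rec.GP == 0.0

    def test_noisy_recovery_within_two_se(self):
        spec = SyntheticSpec(seed=6)
        t, y, phases = simulate_gas_trace(1.61, 0.35, spec, n_cycles=3,
                                          noise_sd=2.0)
        rec = gas_exchange_rates(t, y, phases)
        # noise_sd 2 over 60 points per phase: slope SE ~ 2/sqrt(sum dt^2)
        assert rec.GP == pytest.approx(1.96, abs=0.1)

    def test_positive_dark_slope_clamped_with_warning(self):
        t, y, phases = simulate_gas_trace(1.0, 0.0, SyntheticSpec(seed=7))
        # tilt the dark phase upward
        dark = [(a, b, k) for a, b, k in phases if k == "dark"]
        y = y + np.where(t >= dark[0][0], 0.01 * (t - dark[0][0]), 0.0)
        rec = gas_exchange_rates(t, y, phases)
        assert rec.R_dark == 0.0
        assert rec.warnings

    def test_missing_annotation_rejected(self):
        t, y, phases = simulate_gas_trace(1.0, 0.3, SyntheticSpec(seed=8))
        with pytest.raises(ValueError):
            gas_exchange_rates(t, y, [])

    def test_gp_identity_holds_by_construction(self):
        rec = GasExchangeRecord(NP=2.4, R_dark=0.4)
        assert rec.GP == rec.NP + rec.R_dark


class TestRatios:
    def test_reported_ratios(self):
        rec = GasExchangeRecord(NP=1.96 - 0.35, R_dark=0.35, co2_uptake=0.78)
        pr, pq = photosynthesis_ratios(rec)
        assert round(pr, 1) == 5.6
        assert round(pq, 1) == 2.1

    def test_equal_fluxes_give_unit_pq(self):
        rec = GasExchangeRecord(NP=0.8, R_dark=0.2, co2_uptake=0.8)
        _, pq = photosynthesis_ratios(rec)
        assert pq == pytest.approx(1.0)

    def test_zero_denominators_give_nan_not_exception(self):
        rec = GasExchangeRecord(NP=1.0, R_dark=0.0)
        pr, pq = photosynthesis_ratios(rec)
        assert math.isnan(pr) and math.isnan(pq)


class TestMorphology:
    @pytest.mark.parametrize("d, expected, tol", [
        (2.19, 5.49, 1e-2),    # largest measured cell diameter
        (2.0, 4.18879, 1e-5),
        (0.0, 0.0, 1e-12),
    ])
    def test_sphere_volume(self, d, expected, tol):
        assert sphere_volume(d) == pytest.approx(expected, abs=tol)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            sphere_volume(-1.0)

    def test_content_conversion_and_round_trip(self):
        # 84 mg/gDW in a 5.3 pg cell -> 445 fg per cell
        per_cell = per_gdw_to_per_cell(84.0, 5.3)
        assert per_cell == pytest.approx(445.2, abs=0.1)
        assert per_gdw_to_per_cell(0.0, 5.3) == 0.0
        back = per_cell_to_per_gdw(per_cell, 5.3)
        assert back == pytest.approx(84.0, rel=1e-15)


class TestNutrientBalance:
    def test_steady_state_margin_zero(self):
        df = nutrient_balance(0.1, {"N": 200.0}, {"N": 100.0}, 2.0)
        assert df["margin"].iloc[0] == pytest.approx(0.0)
        assert not df["deficient"].any()

    def test_margin_decreases_with_quota(self):
        margins = [nutrient_balance(0.1, {"P": 50.0}, {"P": q}, 1.0)
                   ["margin"].iloc[0] for q in (10.0, 20.0, 40.0)]
        assert margins[0] > margins[1] > margins[2]

    def test_single_deficient_element_flagged(self):
        medium = {"Na": 300, "N": 250, "S": 50, "Ca": 10, "Mg": 8,
                  "P": 40, "Fe": 1.0}
        quota = {"Na": 5, "N": 100, "S": 6, "Ca": 1, "Mg": 2,
                 "P": 10, "Fe": 2.0}  # iron demand exceeds refill
        df = nutrient_balance(0.05, medium, quota, 1.0)
        flagged = df.loc[df["deficient"], "element"].tolist()
        assert flagged == ["Fe"]

    def test_missing_element_reported_not_fatal(self):
        df = nutrient_balance(0.1, {"N": 100.0}, {"N": 10.0, "Zn": 1.0}, 1.0)
        zn = df[df["element"] == "Zn"].iloc[0]
        assert zn["status"] == "missing in medium"
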