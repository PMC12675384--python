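"""Thermodynamic partition: per-stride heating, envelopes, burn extrapolation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from podotherm.regions import WholeFootSeries
from podotherm.thermo import (
    BurnEstimate,
    StrideSchedule,
    ThermoParams,
    TissueComponent,
    burn_time,
    composite_specific_heat,
    decompose,
    foot_mass_from_body,
    mechanical_curve,
    mechanical_envelope,
    stride_delta_T,
    walking_distance_km,
)


class TestFootMass:
    def test_segment_anthropometry_for_cohort_mean_body_mass(self):
        assert foot_mass_from_body(80.42) == pytest.approx(1.17, abs=0.005)

    def test_hand_arithmetic(self):
        assert foot_mass_from_body(100.0) == pytest.approx(1.45)

    def test_zero_fraction(self):
        assert foot_mass_from_body(70.0, fraction=0.0) == 0.0

    def test_nonpositive_mass_is_error(self):
        with pytest.raises(ValueError):
            foot_mass_from_body(0.0)


class TestCompositeSpecificHeat:
    def test_single_tissue(self):
        assert composite_specific_heat([TissueComponent("soft", 1.0, 1.96)]) == 1.96

    def test_even_mix_of_bone_and_blood(self):
        comps = [TissueComponent("bone", 0.5, 1.31), TissueComponent("blood", 0.5, 3.62)]
        assert composite_specific_heat(comps) == pytest.approx(2.465)

    def test_fraction_sum_violation_reports_deficit(self):
        comps = [TissueComponent("bone", 0.5, 1.31), TissueComponent("blood", 0.4, 3.62)]
        with pytest.raises(ValueError, match="0.1"):
            composite_specific_heat(comps)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=6),
        st.lists(st.floats(min_value=1.31, max_value=3.62), min_size=6, max_size=6),
    )
    def test_convexity(self, weights, cs):
        total = sum(weights)
        comps = [
            TissueComponent(f"t{i}", w / total, c)
            for i, (w, c) in enumerate(zip(weights, cs))
        ]
        val = composite_specific_heat(comps)
        used = [c.c for c in comps]
        assert min(used) - 1e-9 <= val <= max(used) + 1e-9
        assert 1.31 - 1e-9 <= val <= 3.62 + 1e-9


class TestStrideDeltaT:
    def test_mean_inputs(self, thermo_params):
        # -(-0.0034)/(1.17*1.96)
        assert stride_delta_T(thermo_params) == pytest.approx(1.4827e-3, rel=1e-4)

    def test_zero_work(self, thermo_params):
        assert stride_delta_T(thermo_params.replace(W_stride_kJ=0.0)) == 0.0

    def test_positive_net_work_cools(self, thermo_params):
        # upper work bound: net positive work -> small negative change
        assert stride_delta_T(thermo_params.replace(W_stride_kJ=0.00023)) < 0.0


class TestMechanicalCurve:
    def test_full_walk_heating_near_two_and_a_half_degrees(self, thermo_params):
        curve = mechanical_curve(thermo_params)
        assert curve.final_dT == pytest.approx(2.48, abs=0.01)
        assert curve.dT[0] == 0.0

    def test_zero_strides(self, thermo_params):
        params = thermo_params.replace(total_strides=0)
        curve = mechanical_curve(params)
        np.testing.assert_array_equal(curve.dT, 0.0)

    def test_constant_cadence_halfway(self, thermo_params):
        curve = mechanical_curve(thermo_params)
        mid = curve.dT[curve.times == 15.0][0]
        assert mid == pytest.approx(curve.final_dT / 2, rel=1e-9)

    def test_equals_per_stride_accumulation_loop(self, thermo_params):
        curve = mechanical_curve(thermo_params)
        schedule = StrideSchedule.constant_cadence(
            thermo_params.total_strides, thermo_params.duration_min
        )
        per_stride = stride_delta_T(thermo_params)
        for t, expected in zip(curve.times, curve.dT):
            n = int(schedule.cumulative_strides[schedule.times == t][0])
            acc = 0.0
            for _ in range(n):
                acc += per_stride
            assert expected == pytest.approx(acc, rel=1e-12, abs=1e-15)

    def test_linearity_in_work_strides_and_heat_capacity(self, thermo_params):
        base = mechanical_curve(thermo_params).final_dT
        double_W = thermo_params.replace(W_stride_kJ=2 * thermo_params.W_stride_kJ)
        assert mechanical_curve(double_W).final_dT == pytest.approx(2 * base, rel=1e-12)
        double_mc = thermo_params.replace(m_foot_kg=2 * thermo_params.m_foot_kg)
        assert mechanical_curve(double_mc).final_dT == pytest.approx(base / 2, rel=1e-12)
        double_s = thermo_params.replace(total_strides=2 * thermo_params.total_strides)
        assert mechanical_curve(double_s).final_dT == pytest.approx(2 * base, rel=1e-12)

    def test_schedule_mismatch_is_error(self, thermo_params):
        schedule = StrideSchedule.constant_cadence(999, thermo_params.duration_min)
        with pytest.raises(ValueError, match="schedule"):
            mechanical_curve(thermo_params, schedule)


class TestMechanicalEnvelope:
    def test_bounds_bracket_mean_curve(self, thermo_params):
        env = mechanical_envelope(thermo_params)
        mean = mechanical_curve(thermo_params)
        # low work = more dissipation = hottest; high c = slowest heating
        assert np.all(env.work_low.dT >= mean.dT - 1e-12)
        assert np.all(env.work_high.dT <= mean.dT + 1e-12)
        assert np.all(env.c_low.dT >= mean.dT - 1e-12)
        assert np.all(env.c_high.dT <= mean.dT + 1e-12)

    def test_upper_work_bound_gives_slight_cooling(self, thermo_params):
        env = mechanical_envelope(thermo_params)
        assert env.work_high.final_dT < 0.0
        assert env.work_high.final_dT > -0.5

    def test_low_work_bound_magnitude(self, thermo_params):
        env = mechanical_envelope(thermo_params)
        # 0.0071*1674/(1.17*1.96)
        assert env.work_low.final_dT == pytest.approx(5.18, abs=0.01)

    def test_bounds_equal_to_means_collapse(self, thermo_params):
        params = thermo_params.replace(
            W_bounds=(thermo_params.W_stride_kJ, thermo_params.W_stride_kJ),
            c_bounds=(thermo_params.c_foot_kJ_per_kgK, thermo_params.c_foot_kJ_per_kgK),
        )
        env = mechanical_envelope(params)
        mean = mechanical_curve(thermo_params)
        for curve in (env.work_low, env.work_high, env.c_low, env.c_high):
            np.testing.assert_allclose(curve.dT, mean.dT, rtol=1e-14)

    def test_missing_bounds_named_in_error(self, thermo_params):
        with pytest.raises(ValueError, match="W_bounds"):
            mechanical_envelope(thermo_params.replace(W_bounds=None))
        with pytest.raises(ValueError, match="c_bounds"):
            mechanical_envelope(thermo_params.replace(c_bounds=None))


class TestDecompose:
    def _series(self, times, delta, baseline=30.0):
        return WholeFootSeries(np.asarray(times, float), baseline + np.asarray(delta, float))

    def test_final_values_split_as_reported(self, thermo_params, walk_times):
        # experimental rise of 3.50 degC split against the mechanical estimate
        mech = mechanical_curve(
            thermo_params,
            StrideSchedule.constant_cadence(1674, 30.0, times=walk_times),
        )
        delta = np.linspace(0, 3.50, walk_times.size)
        result = decompose(self._series(walk_times, delta), mech)
        assert result.dT_mech[-1] == pytest.approx(2.48, abs=0.01)
        assert result.dT_phys[-1] == pytest.approx(1.0, abs=0.05)

    def test_mech_equal_exp_gives_zero_phys(self, thermo_params, walk_times):
        mech = mechanical_curve(
            thermo_params, StrideSchedule.constant_cadence(1674, 30.0, times=walk_times)
        )
        result = decompose(self._series(walk_times, mech.dT), mech)
        np.testing.assert_allclose(result.dT_phys, 0.0, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_conservation_identity_on_random_curves(self, seed):
        from podotherm.thermo import MechanicalCurve

        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        t = np.concatenate([[0.0], np.cumsum(rng.uniform(0.5, 5.0, n - 1))])
        d_exp = np.concatenate([[0.0], rng.normal(0, 2, n - 1)])
        d_mech = np.concatenate([[0.0], rng.normal(0, 2, n - 1)])
        result = decompose(
            WholeFootSeries(t, 31.0 + d_exp), MechanicalCurve(t, d_mech)
        )
        np.testing.assert_allclose(
            result.dT_mech + result.dT_phys, result.dT_exp, rtol=1e-15, atol=1e-15
        )
        assert result.dT_exp[0] == result.dT_mech[0] == result.dT_phys[0] == 0.0

    def test_grid_mismatch_requires_interpolation(self, thermo_params, walk_times):
        mech = mechanical_curve(thermo_params)  # 5-min grid
        fine = np.arange(0.0, 31.0, 1.0)
        series = self._series(fine, np.linspace(0, 3.5, fine.size))
        with pytest.raises(ValueError, match="interpolate"):
            decompose(series, mech)
        result = decompose(series, mech, interpolate=True)
        assert result.dT_phys.shape == fine.shape
        # interpolated mechanical curve still hits the anchored values
        assert result.dT_mech[-1] == pytest.approx(mech.final_dT, rel=1e-12)

    def test_envelope_propagation(self, thermo_params, walk_times):
        schedule = StrideSchedule.constant_cadence(1674, 30.0, times=walk_times)
        mech = mechanical_curve(thermo_params, schedule)
        env = mechanical_envelope(thermo_params, schedule)
        series = self._series(walk_times, np.linspace(0, 3.5, walk_times.size))
        result = decompose(series, mech, envelope=env)
        assert set(result.phys_envelopes) == {
            "phys_low_work",
            "phys_high_work",
            "phys_low_c",
            "phys_high_c",
        }
        # hotter mechanical bound -> colder physiological residual
        np.testing.assert_allclose(
            result.phys_envelopes["phys_low_work"],
            result.dT_exp - env.work_low.dT,
            rtol=1e-12,
        )
        assert np.all(result.phys_envelopes["phys_low_work"] <= result.dT_phys + 1e-12)


class TestBurnTime:
    def test_mean_mechanical_rate_from_baseline_thirty(self, thermo_params):
        rate = mechanical_curve(thermo_params).rate_per_min
        est = burn_time(30.0, rate)
        assert est.time_to_threshold_min == pytest.approx(160.8, abs=0.5)

    def test_baseline_at_threshold(self):
        assert burn_time(43.3, 0.1).time_to_threshold_min == 0.0

    def test_zero_rate_never_reaches(self):
        est = burn_time(30.0, 0.0)
        assert not est.reaches_threshold
        assert est.to_dict()["time_to_threshold_min"] == "never"

    def test_experimental_then_mechanical_mode(self, walk_times):
        temps = 30.0 + np.linspace(0, 3.5, walk_times.size)
        series = WholeFootSeries(walk_times, temps)
        est = burn_time(
            30.0, 0.0827, mode="experimental_then_mechanical", exp_series=series
        )
        expected = 30.0 + (43.3 - 33.5) / 0.0827
        assert est.time_to_threshold_min == pytest.approx(expected, rel=1e-9)

    def test_experimental_crossing_interpolated(self):
        series = WholeFootSeries(np.array([0.0, 10.0]), np.array([42.0, 44.0]))
        est = burn_time(42.0, 0.1, mode="experimental_then_mechanical", exp_series=series)
        assert est.time_to_threshold_min == pytest.approx(6.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=20.0, max_value=43.0),
        st.floats(min_value=1e-3, max_value=1.0),
        st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_strictly_decreasing_in_rate_and_baseline(self, baseline, rate, bump):
        t0 = burn_time(baseline, rate).time_to_threshold_min
        assert burn_time(baseline, rate + bump).time_to_threshold_min < t0
        assert burn_time(baseline + bump, rate).time_to_threshold_min < t0

    def test_unknown_mode_is_error(self):
        with pytest.raises(ValueError, match="mode"):
            burn_time(30.0, 0.1, mode="bogus")


class TestWalkingDistance:
    def test_printed_threshold_times_convert_to_km(self):
        assert walking_distance_km(160.0, 1.25) == pytest.approx(12.0)
        assert walking_distance_km(77.5, 1.25) == pytest.approx(5.8125)

    def test_never_propagates(self):
        assert walking_distance_km(math.inf, 1.25) == math.inf


class TestScheduleAndParams:
    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            StrideSchedule(np.array([0.0, 5.0]), np.array([10.0, 5.0]))
        with pytest.raises(ValueError):
            StrideSchedule(np.array([5.0, 10.0]), np.array([0.0, 10.0]))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ThermoParams(-0.003, 0.0, 1.96, 1674, 30.0)
        with pytest.raises(ValueError):
            ThermoParams(-0.003, 1.17, 1.96, 1674, 30.0, W_bounds=(1.0, -1.0))

    def test_config_roundtrip(self, thermo_params, tmp_path):
        import yaml

        cfg = {
            "W_stride_kJ": -0.0034,
            "m_foot_kg": 1.17,
            "c_foot_kJ_per_kgK": 1.96,
            "total_strides": 1674,
            "duration_min": 30.0,
            "W_bounds": [-0.0071, 0.00023],
            "c_bounds": [1.31, 3.62],
        }
        path = tmp_path / "thermo.yaml"
        path.write_text(yaml.safe_dump(cfg))
        from podotherm.thermo import load_thermo_config

        assert ThermoParams.from_config(load_thermo_config(path)) == thermo_params
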