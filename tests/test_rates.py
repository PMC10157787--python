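"""Per-fish metabolic-rate estimators against closed forms and brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aeroscope as a
from conftest import brute_force_mmr_slope


class TestMMRChase:
    def test_exact_line_all_windows_tie(self):
        t = np.arange(0, 300.0)
        o2 = 10.0 - 0.002 * t
        est = a.estimate_mmr_chase(t, o2, v_r=98.0, v_f=3.5, m=3.5)
        expected = a.compute_mo2(0.002 * 60, 98.0, 3.5, 3.5)
        assert est.value == pytest.approx(expected, rel=1e-9)

    def test_two_phase_decay_picks_early_window(self):
        # steep first 100 s, shallow afterwards: the steepest >=90 s window
        # starts at 0; brute force confirms
        t = np.arange(0, 300.0)
        o2 = np.where(t < 100, 10.0 - 0.004 * t, 9.6 - 0.001 * (t - 100))
        est = a.estimate_mmr_chase(t, o2, v_r=98.0, v_f=3.5, m=3.5)
        oracle = brute_force_mmr_slope(t, o2)
        assert est.value == pytest.approx(
            a.compute_mo2(abs(oracle) * 60, 98.0, 3.5, 3.5), rel=1e-9)

    def test_white_noise_yields_missing(self, rng):
        t = np.arange(0, 300.0)
        o2 = 9.0 + rng.normal(0, 0.05, len(t))
        est = a.estimate_mmr_chase(t, o2, v_r=98.0, v_f=3.5, m=3.5)
        assert est.is_missing and "r2" in est.reason

    def test_short_cycle_missing_with_reason(self):
        t = np.arange(0, 60.0)
        est = a.estimate_mmr_chase(t, 10.0 - 0.001 * t, v_r=98.0, v_f=3.5, m=3.5)
        assert est.is_missing and "shorter" in est.reason

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_fixtures(self, seed):
        """Sliding-window search equals naive enumeration over every window."""
        rng = np.random.default_rng(seed)
        t = np.arange(0, 150.0, 1.0)
        k = rng.uniform(0.005, 0.02)
        o2 = 10.0 - rng.uniform(0.1, 0.5) * (1 - np.exp(-k * t)) / k * 0.05
        o2 = o2 + rng.normal(0, 0.003, len(t))
        est = a.estimate_mmr_chase(t, o2, v_r=98.0, v_f=3.5, m=3.5)
        oracle = brute_force_mmr_slope(t, o2)
        if oracle is None:
            assert est.is_missing
        else:
            assert est.value == pytest.approx(
                a.compute_mo2(abs(oracle) * 60, 98.0, 3.5, 3.5), rel=1e-9)


class TestMMROverall:
    def test_max_at_chase(self):
        overnight = np.linspace(3.0, 2.0, 70)
        est = a.estimate_mmr_overall(overnight, mmr_1h=10.0, mmr_18h=9.0)
        assert est.value == 10.0

    def test_overnight_burst_dominates(self):
        overnight = np.concatenate([np.linspace(5.0, 2.0, 70), [12.5]])
        est = a.estimate_mmr_overall(overnight, mmr_1h=10.0)
        assert est.value == 12.5

    def test_59_values_missing_with_reason(self):
        est = a.estimate_mmr_overall(np.full(59, 3.0), mmr_1h=10.0)
        assert est.is_missing and "59" in est.reason
        # exactly 60 is still too few ("more than 60" rule)
        assert a.estimate_mmr_overall(np.full(60, 3.0)).is_missing
        assert not a.estimate_mmr_overall(np.full(61, 3.0)).is_missing


class TestRMR:
    def test_constant_series(self):
        est = a.estimate_rmr(np.full(80, 3.0))
        assert est.value == pytest.approx(3.0)

    def test_mostly_low_with_high_tail(self):
        vals = np.concatenate([np.full(90, 3.0), np.full(10, 6.0)])
        assert a.estimate_rmr(vals).value == pytest.approx(3.0)

    def test_linear_interpolation_convention(self):
        vals = np.arange(1.0, 101.0)  # 1..100
        # brute-force oracle: numpy's linear-interpolated quantile
        assert a.estimate_rmr(vals).value == pytest.approx(10.9)

    def test_decile_mean_variant(self):
        vals = np.arange(1.0, 101.0)
        est = a.estimate_rmr(vals, method="decile_mean")
        assert est.value == pytest.approx(np.mean([i for i in range(1, 11)]), rel=0.05)

    def test_r2_filter_and_eligibility(self):
        vals = np.full(100, 3.0)
        r2 = np.concatenate([np.full(50, 0.95), np.full(50, 0.5)])
        est = a.estimate_rmr(vals, r_squared=r2)
        assert est.is_missing and "50" in est.reason


class TestAerobicScope:
    def test_printed_group_mean_aas(self):
        scope = a.aerobic_scope(11.26, 2.70, survived=True)
        assert scope.aas == pytest.approx(8.56)

    def test_printed_group_mean_fas(self):
        scope = a.aerobic_scope(11.41, 2.06, survived=True)
        assert scope.fas == pytest.approx(5.54, abs=0.005)

    def test_mortality_rule_zeroes_everything(self):
        scope = a.aerobic_scope(11.26, 2.70, survived=False)
        assert scope.aas == 0.0 and scope.fas == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(mmr=st.floats(0.1, 30.0) | st.just(float("nan")),
           rmr=st.floats(0.1, 30.0) | st.just(float("nan")))
    def test_mortality_output_independent_of_rates(self, mmr, rmr):
        scope = a.aerobic_scope(mmr, rmr, survived=False)
        assert scope == a.aerobic_scope(1.0, 1.0, survived=False)

    def test_inverted_survivor_flagged(self):
        scope = a.aerobic_scope(2.0, 3.0, survived=True)
        assert scope.flagged and scope.aas == pytest.approx(-1.0)


class TestMassAdjust:
    def test_reference_mass_identity(self):
        assert a.mass_adjust(5.0, 3.5, 0.58) == pytest.approx(5.0)

    def test_double_mass_mmr_exponent(self):
        assert a.mass_adjust(1.0, 7.0, 0.58) == pytest.approx(2 ** 0.42, rel=1e-12)

    def test_half_mass_rmr_exponent(self):
        assert a.mass_adjust(1.0, 1.75, 0.67) == pytest.approx(0.5 ** 0.33, rel=1e-12)


class TestQ10:
    def test_doubling_over_ten_degrees(self):
        assert a.compute_q10(2.0, 12.0, 4.0, 22.0) == pytest.approx(2.0)

    def test_closed_form(self):
        assert a.compute_q10(2.0, 12.0, 3.0, 18.0) == pytest.approx(
            1.5 ** (10.0 / 6.0), rel=1e-12)

    def test_exponent_one_when_span_is_ten(self):
        assert a.compute_q10(2.3, 12.0, 3.1, 22.0) == pytest.approx(3.1 / 2.3)

    def test_equal_temperatures_rejected(self):
        with pytest.raises(ValueError):
            a.compute_q10(2.0, 12.0, 3.0, 12.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(r12=st.floats(0.5, 5.0), q10=st.floats(1.1, 3.0),
           tx=st.floats(13.0, 28.0))
    def test_round_trip_identity(self, r12, q10, tx):
        """Generating a rate with a known Q10 and re-estimating recovers it."""
        rx = r12 * q10 ** ((tx - 12.0) / 10.0)
        assert a.compute_q10(r12, 12.0, rx, tx) == pytest.approx(q10, rel=1e-9)


class TestScalingExponent:
    def test_noiseless_recovery(self):
        mass = np.linspace(1.4, 7.2, 30)
        mo2 = 3.0 * mass ** 0.58
        b, _ = a.estimate_scaling_exponent(mass, mo2)
        assert b == pytest.approx(0.58, abs=1e-10)

    def test_noisy_recovery_within_band(self):
        rng = np.random.default_rng(77)
        mass = rng.uniform(1.4, 7.2, 200)
        mo2 = 3.0 * mass ** 0.58 * rng.lognormal(0.0, 0.1, 200)
        b, _ = a.estimate_scaling_exponent(mass, mo2)
        assert b == pytest.approx(0.58, abs=0.05)

    def test_shared_slope_across_groups(self):
        mass = np.concatenate([np.linspace(1.5, 7.0, 20)] * 2)
        groups = ["a"] * 20 + ["b"] * 20
        mo2 = np.concatenate([2.0 * mass[:20] ** 0.58, 4.0 * mass[20:] ** 0.58])
        b, intercepts = a.estimate_scaling_exponent(mass, mo2, groups=groups)
        assert b == pytest.approx(0.58, abs=1e-10)
        assert intercepts["b"] - intercepts["a"] == pytest.approx(np.log10(2.0))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            a.estimate_scaling_exponent([3.5, 3.5, 3.5], [5, 5, 5])
        with pytest.raises(ValueError):
            a.estimate_scaling_exponent([1.0, 2.0], [1.0, 2.0])


class TestGroupSummary:
    def test_fas_is_mean_of_ratios_not_ratio_of_means(self):
        df = pd.DataFrame({
            "population": ["p"] * 2, "test_temperature": [12.0] * 2,
            "rmr": [2.0, 4.0], "mmr_overall": [10.0, 12.0],
            "aas": [8.0, 8.0], "fas": [5.0, 3.0],
        })
        out = a.group_summary(df)
        assert out["fas_mean"].iloc[0] == pytest.approx(4.0)  # not 22/6
        assert out["aas_sem"].iloc[0] == pytest.approx(0.0)
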