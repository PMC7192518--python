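import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from valueddm import ddm_core as dc

TABLE_PARAMS = dc.DDMParams(alpha=3.37, tau=0.945, z=0.531)


class TestSoftmax:
    def test_zero_temperature_gives_chance(self):
        assert dc.softmax_p_choice(90.0, 10.0, beta=0.0) == pytest.approx(0.5)

    def test_equal_values_give_chance(self):
        assert dc.softmax_p_choice(42.0, 42.0, beta=3.0) == pytest.approx(0.5)

    def test_log_three_separation_gives_three_quarters(self):
        assert dc.softmax_p_choice(np.log(3.0), 0.0, beta=1.0) == pytest.approx(0.75)

    def test_stable_for_extreme_values(self):
        assert dc.softmax_p_choice(1e6, 0.0, beta=10.0) == pytest.approx(1.0)
        assert dc.softmax_p_choice(-1e6, 0.0, beta=10.0) == pytest.approx(0.0)


class TestDriftMaps:
    def test_linear_map(self):
        assert dc.drift_linear(0.0, 0.7) == 0.0
        assert dc.drift_linear(5.0, 0.2) == pytest.approx(1.0)
        assert dc.drift_linear(-3.0, 0.2) == -dc.drift_linear(3.0, 0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(m=st.floats(-50, 50), vc=st.floats(0.01, 5), vm=st.floats(0.1, 10))
    def test_sigmoid_is_odd_and_bounded(self, m, vc, vm):
        v = dc.drift_sigmoid(m, vc, vm)
        assert abs(v) <= vm
        if abs(m * vc) < 30:  # away from floating-point saturation
            assert abs(v) < vm
        assert v == pytest.approx(-dc.drift_sigmoid(-m, vc, vm), abs=1e-12)

    def test_sigmoid_asymptotes(self):
        assert dc.drift_sigmoid(1e4, 1.0, 2.5) == pytest.approx(2.5)
        assert dc.drift_sigmoid(-1e4, 1.0, 2.5) == pytest.approx(-2.5)

    def test_small_signal_slope_matches_linear_map(self):
        # d/dx S(vc*x) at 0 equals vmax*vc/2, so a linear map with
        # v_coeff = vmax*vc/2 matches the sigmoid map locally
        vm_, vc = 1.8, 0.6
        eps = 1e-6
        slope_s = dc.drift_sigmoid(eps, vc, vm_) / eps
        slope_lin = dc.drift_linear(eps, vm_ * vc / 2.0) / eps
        assert slope_s == pytest.approx(slope_lin, rel=1e-4)


class TestWienerDensity:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.5, 4.5), z=st.floats(0.15, 0.85),
           v=st.floats(-3, 3), t=st.floats(0.2, 6.0))
    def test_reflection_symmetry_exact(self, a, z, v, t):
        p = dc.DDMParams(alpha=a, tau=0.1, z=z)
        p_ref = dc.DDMParams(alpha=a, tau=0.1, z=1 - z)
        up = dc.wfpt_logdensity(t, p, v)
        low = dc.wfpt_logdensity(-t, p_ref, -v)
        assert up == low

    @pytest.mark.parametrize("v", [-1.5, 0.0, 1.0])
    def test_total_probability_integrates_to_one(self, v):
        up = quad(lambda t: np.exp(dc.wfpt_logdensity(t, TABLE_PARAMS, v)),
                  TABLE_PARAMS.tau, 120, limit=200)[0]
        low = quad(lambda t: np.exp(dc.wfpt_logdensity(-t, TABLE_PARAMS, v)),
                   TABLE_PARAMS.tau, 120, limit=200)[0]
        assert up + low == pytest.approx(1.0, abs=1e-4)

    def test_density_zero_at_or_below_nondecision_time(self):
        assert dc.wfpt_logdensity(0.5, TABLE_PARAMS, 1.0) == -np.inf
        assert dc.wfpt_logdensity(-0.2, TABLE_PARAMS, 1.0) == -np.inf

    def test_matches_euler_simulation_histogram(self):
        sim = dc.simulate_trials(TABLE_PARAMS, np.full(150_000, 1.0), seed=11)
        upper = sim[(sim["boundary"] == "upper") & ~sim["censored"]]
        width = 0.1
        frac = ((upper["rt"] - 2.0).abs() < width / 2).sum() / len(sim)
        analytic = np.exp(dc.wfpt_logdensity(2.0, TABLE_PARAMS, 1.0))
        assert frac / width == pytest.approx(analytic, abs=0.02)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            dc.wfpt_logdensity(1.0, dc.DDMParams(alpha=-1, tau=0.5, z=0.5), 0.0)
        with pytest.raises(ValueError):
            dc.wfpt_logdensity(1.0, dc.DDMParams(alpha=2, tau=0.5, z=1.5), 0.0)


class TestAbsorptionProbability:
    def test_neutral_bias_zero_drift_is_chance(self):
        assert dc.p_upper(dc.DDMParams(2.0, 0.3, 0.5), 0.0) == pytest.approx(0.5)

    def test_zero_drift_limit_equals_start_point(self):
        assert dc.p_upper(dc.DDMParams(2.0, 0.3, 0.531), 0.0) == pytest.approx(0.531)
        assert dc.p_upper(dc.DDMParams(2.0, 0.3, 0.531), 1e-12) == pytest.approx(0.531)

    def test_strong_drift_is_certain(self):
        assert dc.p_upper(dc.DDMParams(2.0, 0.3, 0.5), 50.0) == pytest.approx(1.0)
        assert dc.p_upper(dc.DDMParams(2.0, 0.3, 0.5), -50.0) == pytest.approx(0.0)

    def test_matches_simulation(self):
        p = dc.DDMParams(alpha=2.0, tau=0.3, z=0.5)
        sim = dc.simulate_trials(p, np.full(100_000, 0.5), seed=5)
        frac = (sim["boundary"] == "upper").mean()
        assert frac == pytest.approx(dc.p_upper(p, 0.5), abs=0.006)


class TestSimulator:
    def test_rts_exceed_nondecision_time(self):
        sim = dc.simulate_trials(TABLE_PARAMS, np.full(500, 0.5), seed=2)
        assert (sim["rt"] > TABLE_PARAMS.tau).all()

    def test_seed_determinism(self):
        a = dc.simulate_trials(TABLE_PARAMS, np.full(200, 1.0), seed=8)
        b = dc.simulate_trials(TABLE_PARAMS, np.full(200, 1.0), seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_signed_rt_matches_boundary(self):
        sim = dc.simulate_trials(TABLE_PARAMS, np.full(300, 0.0), seed=3)
        up = sim["boundary"] == "upper"
        assert (sim.loc[up, "signed_rt"] > 0).all()
        assert (sim.loc[~up, "signed_rt"] < 0).all()

    def test_stronger_drift_speeds_responses(self):
        slow = dc.simulate_trials(TABLE_PARAMS, np.full(3000, 0.2), seed=4)
        fast = dc.simulate_trials(TABLE_PARAMS, np.full(3000, 3.0), seed=4)
        assert fast["rt"].mean() < slow["rt"].mean()

    def test_single_trial_wrapper(self):
        b, rt = dc.simulate_trial(TABLE_PARAMS, 1.0, seed=1)
        assert b in ("upper", "lower") and rt > TABLE_PARAMS.tau


class TestTrimming:
    def _table(self, n, seed=0):
        rng = np.random.default_rng(seed)
        rt = rng.gamma(4.0, 0.5, n) + 0.5
        return pd.DataFrame({"subject_id": "s1", "rt": rt,
                             "signed_rt": rt * rng.choice([-1, 1], n)})

    def test_default_fraction_removes_five_each_side_of_200(self):
        out = dc.trim_rts(self._table(200))
        assert len(out) == 190

    def test_zero_fraction_is_identity(self):
        t = self._table(50)
        out = dc.trim_rts(t, fraction=0.0)
        pd.testing.assert_frame_equal(out, t)

    def test_retained_rows_are_an_unchanged_subset(self):
        t = self._table(120)
        out = dc.trim_rts(t)
        assert set(out["rt"]).issubset(set(t["rt"]))
        assert out["rt"].min() > t["rt"].min()
        assert out["rt"].max() < t["rt"].max()

    def test_per_subject_trimming(self):
        a, b = self._table(200, seed=1), self._table(200, seed=2)
        b["subject_id"] = "s2"
        out = dc.trim_rts(pd.concat([a, b], ignore_index=True))
        assert (out.groupby("subject_id").size() == 190).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dc.trim_rts(pd.DataFrame(columns=["subject_id", "rt"]))

    def test_absolute_filter_bounds(self):
        t = pd.DataFrame({"rt": [0.2, 0.5, 3.0, 12.0], "signed_rt": [0.2, -0.5, 3.0, 12.0]})
        out = dc.absolute_rt_filter(t)
        assert out["rt"].tolist() == [0.5, 3.0]
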