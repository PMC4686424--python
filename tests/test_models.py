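"""Tests of the three stop-trial generators and dataset simulation."""
import numpy as np
import pandas as pd
import pytest

from nestedrace.models import (
    simulate_dataset,
    simulate_go_batch,
    simulate_go_trial,
    simulate_stop_batch,
)
from nestedrace.params import ModulationSpec, ProcessParams, SimConfig, TaskDesign
from nestedrace.presets import PROACTIVE_PARAMS, proactive_params_by_cue

from conftest import TINY_SIGMA


class TestGoTrials:
    def test_noise_free_closed_form_rt(self):
        # xb=0: rt = tr + a/v_e = 0.174 + 0.534/1.266 = 0.596
        p = ProcessParams(a=0.534, tr=0.174, v_e=1.266, sigma=TINY_SIGMA)
        cfg = SimConfig(dt=0.001, deadline=0.650)
        out = simulate_go_trial(p, cfg, seed=0)
        assert out.responded
        assert out.rt == pytest.approx(0.596, abs=2 * cfg.dt)

    def test_fast_drift_always_responds_and_zero_drift_never(self):
        cfg = SimConfig(dt=0.001, deadline=0.650)
        fast = ProcessParams(a=0.3, tr=0.1, v_e=5.0, sigma=0.01)
        assert simulate_go_batch(fast, cfg, 500, seed=1).p_respond == 1.0
        still = ProcessParams(a=0.3, tr=0.1, v_e=0.0, sigma=TINY_SIGMA)
        assert simulate_go_batch(still, cfg, 500, seed=2).p_respond == 0.0


class TestDpmStopTrials:
    def test_ssd_at_deadline_reduces_exactly_to_go_trials(self, dpm_params):
        cfg = SimConfig(dt=0.001, deadline=0.650)
        go = simulate_go_batch(dpm_params, cfg, 2_000, seed=42)
        stop = simulate_stop_batch("dpm", dpm_params, 0.650, cfg, 2_000, seed=42)
        np.testing.assert_array_equal(go.responded, stop.responded)
        np.testing.assert_array_equal(go.rt, stop.rt)

    def test_noise_free_instant_brake_always_stops(self):
        p = ProcessParams(a=0.534, tr=0.174, v_e=1.266, v_b=500.0, sigma=TINY_SIGMA)
        cfg = SimConfig(dt=0.001, deadline=0.650)
        b = simulate_stop_batch("dpm", p, 0.300, cfg, 100, seed=3)
        assert b.p_respond == 0.0

    def test_stop_before_onset_always_stops(self, dpm_params):
        # braking starts at theta_e = 0, already at its boundary
        cfg = SimConfig(dt=0.001, deadline=0.650)
        b = simulate_stop_batch("dpm", dpm_params, 0.050, cfg, 500, seed=4)
        assert b.p_respond == 0.0

    def test_negative_ssd_rejected(self, dpm_params):
        cfg = SimConfig(dt=0.001, deadline=0.650)
        with pytest.raises(ValueError):
            simulate_stop_batch("dpm", dpm_params, -0.1, cfg, 10, seed=0)


class TestIndependentStopTrials:
    def test_zero_brake_drift_never_stops(self):
        p = ProcessParams(a=0.5, tr=0.1, v_e=1.0, v_b=0.0, sigma=TINY_SIGMA)
        cfg = SimConfig(dt=0.001, deadline=0.650)
        b = simulate_stop_batch("independent", p, 0.2, cfg, 200, seed=5)
        assert b.p_respond == 1.0

    @pytest.mark.parametrize(
        "v_b,should_stop",
        [(2.0, True), (1.0, False)],  # brake at 0.2+0.5/v_b vs exec at 0.6
    )
    def test_noise_free_race_follows_closed_form_crossing_times(self, v_b, should_stop):
        p = ProcessParams(a=0.5, tr=0.1, v_e=1.0, v_b=v_b, sigma=TINY_SIGMA)
        cfg = SimConfig(dt=0.001, deadline=0.650)
        b = simulate_stop_batch("independent", p, 0.2, cfg, 50, seed=6)
        assert (b.p_respond == 0.0) == should_stop


class TestInteractiveStopTrials:
    def test_missing_sso_rejected(self, dpm_params):
        cfg = SimConfig(dt=0.001, deadline=0.650)
        with pytest.raises(ValueError):
            simulate_stop_batch("interactive", dpm_params, 0.3, cfg, 10, seed=0)

    def test_late_suppression_reduces_exactly_to_go_trials(self):
        p = ProcessParams(a=0.445, tr=0.220, v_e=1.195, v_b=3.023, xb=1.474, sso=5.0)
        cfg = SimConfig(dt=0.001, deadline=0.650)
        go = simulate_go_batch(p, cfg, 2_000, seed=7)
        stop = simulate_stop_batch("interactive", p, 0.3, cfg, 2_000, seed=7)
        np.testing.assert_array_equal(go.responded, stop.responded)
        np.testing.assert_array_equal(go.rt, stop.rt)

    def test_noise_free_strong_brake_vetoes_subthreshold_trials(self):
        # exec crosses at 0.6; suppression arrives at ssd+sso=0.45 < 0.6
        p = ProcessParams(a=0.5, tr=0.1, v_e=1.0, v_b=50.0, sigma=TINY_SIGMA, sso=0.15)
        cfg = SimConfig(dt=0.001, deadline=0.650)
        b = simulate_stop_batch("interactive", p, 0.30, cfg, 50, seed=8)
        assert b.p_respond == 0.0

    def test_response_before_suppression_onset_stands(self):
        # exec crosses at 0.6 < ss_tr = 0.62, brake arbitrarily strong
        p = ProcessParams(a=0.5, tr=0.1, v_e=1.0, v_b=500.0, sigma=TINY_SIGMA, sso=0.22)
        cfg = SimConfig(dt=0.001, deadline=0.650)
        b = simulate_stop_batch("interactive", p, 0.40, cfg, 50, seed=9)
        assert b.p_respond == 1.0
        assert np.allclose(b.rts, 0.6, atol=0.002)


@pytest.mark.parametrize("model", ["dpm", "independent", "interactive"])
def test_stop_probability_non_increasing_in_ssd(model, reactive_design):
    from nestedrace.presets import REACTIVE_PARAMS

    p = REACTIVE_PARAMS[model]
    cfg = SimConfig(dt=0.001, deadline=reactive_design.deadline)
    p_stop = [
        1.0 - simulate_stop_batch(model, p, ssd, cfg, 10_000, seed=100 + i).p_respond
        for i, ssd in enumerate(reactive_design.ssds)
    ]
    # Monte-Carlo slack: ~3 binomial SEs at n=10,000
    assert np.all(np.diff(p_stop) <= 0.015), p_stop


class TestSimulateDataset:
    def _spec(self):
        return ModulationSpec(model_kind="dpm", free_params=(), conditions=("pooled",))

    def test_zero_trials_gives_empty_table(self, reactive_design, dpm_params):
        cfg = SimConfig(deadline=0.650, n_trials=0)
        table = simulate_dataset(
            self._spec(), reactive_design, {"pooled": dpm_params}, cfg, seed=1,
            n_go=0, n_stop_per_ssd=0,
        )
        assert len(table) == 0

    def test_fixed_seed_reproduces_table_exactly(self, reactive_design, dpm_params):
        cfg = SimConfig(deadline=0.650, n_trials=200)
        t1 = simulate_dataset(self._spec(), reactive_design, {"pooled": dpm_params}, cfg, seed=9)
        t2 = simulate_dataset(self._spec(), reactive_design, {"pooled": dpm_params}, cfg, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_modulation_violation_rejected(self, reactive_design, dpm_params):
        spec = ModulationSpec(
            model_kind="dpm", free_params=("v_e",), conditions=("baseline", "caution")
        )
        bad = {
            "baseline": dpm_params,
            "caution": dpm_params.replace(v_e=1.1, a=0.6),  # a not free
        }
        cfg = SimConfig(deadline=0.650, n_trials=10)
        with pytest.raises(ValueError, match="'a'"):
            simulate_dataset(spec, reactive_design, bad, cfg, seed=0)

    def test_proactive_response_rate_rises_with_cue(self, proactive_design):
        params = proactive_params_by_cue("drift")
        conds = tuple(f"p{int(c*100)}" for c in proactive_design.cues)
        spec = ModulationSpec(
            model_kind="dpm", free_params=("v_e",), conditions=conds
        )
        cfg = SimConfig(deadline=proactive_design.deadline, n_trials=2_000)
        table = simulate_dataset(
            spec, proactive_design, dict(zip(conds, params)), cfg, seed=21
        )
        rates = table.groupby("cue")["response"].mean()
        assert rates.is_monotonic_increasing, rates

    def test_trial_invariants_hold(self, reactive_design, dpm_params):
        cfg = SimConfig(deadline=0.650, n_trials=500)
        table = simulate_dataset(self._spec(), reactive_design, {"pooled": dpm_params}, cfg, seed=3)
        responded = table["response"] == 1
        assert table.loc[responded, "rt"].gt(dpm_params.tr).all()
        assert table.loc[responded, "rt"].le(0.650).all()
        assert table.loc[~responded, "rt"].isna().all()
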