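"""Tests for trial-table summaries, quantiles, and the logistic PSE."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestedrace.stats import (
    LogisticFit,
    ObservedSummary,
    average_summaries,
    logistic_pse,
    rt_quantiles,
    summarize,
)


def _interp_quantile_oracle(xs, p):
    """Independent linear-interpolation quantile (type 7) implementation."""
    xs = sorted(xs)
    h = (len(xs) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestRtQuantiles:
    def test_constant_sample(self):
        np.testing.assert_allclose(rt_quantiles([0.5] * 8), np.full(5, 0.5))

    def test_matches_independent_interpolation_oracle(self):
        xs = np.arange(0.1, 1.05, 0.1)  # 0.1 .. 1.0
        got = rt_quantiles(xs)
        expected = [_interp_quantile_oracle(xs, p) for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_duplicating_max_leaves_low_quantile_nearly_unchanged(self):
        xs = list(np.arange(0.1, 1.05, 0.1))
        q1 = rt_quantiles(xs)[0]
        q2 = rt_quantiles(xs + [1.0])[0]
        assert q2 >= q1  # adding mass at the top cannot lower the 0.1 quantile

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rt_quantiles([])

    @given(st.lists(st.floats(min_value=0.01, max_value=2.0), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_output_non_decreasing(self, xs):
        q = rt_quantiles(xs)
        assert np.all(np.diff(q) >= 0)


def _hand_table():
    """20 reactive trials with hand-computable summaries."""
    rows = []
    # 10 go trials: 8 responses at 0.50..0.57, 2 omissions
    for i in range(8):
        rows.append(("s0", "pooled", "reactive", "go", np.nan, np.nan, 1, 0.50 + 0.01 * i))
    for _ in range(2):
        rows.append(("s0", "pooled", "reactive", "go", np.nan, np.nan, 0, np.nan))
    # 10 stop trials: ssd 0.2 (4 trials, all stopped), ssd 0.4 (6 trials, 3 responded)
    for _ in range(4):
        rows.append(("s0", "pooled", "reactive", "stop", 0.2, np.nan, 0, np.nan))
    for rt in (0.58, 0.60, 0.62):
        rows.append(("s0", "pooled", "reactive", "stop", 0.4, np.nan, 1, rt))
    for _ in range(3):
        rows.append(("s0", "pooled", "reactive", "stop", 0.4, np.nan, 0, np.nan))
    return pd.DataFrame(
        rows,
        columns=["subject", "condition", "task", "trial_type", "ssd", "cue", "response", "rt"],
    )


class TestSummarize:
    def test_hand_built_reactive_table(self, reactive_design):
        s = summarize(_hand_table(), reactive_design)
        assert s.p_go == pytest.approx(0.8)
        assert s.p_corr == pytest.approx(0.8)
        assert s.p_err == pytest.approx(0.3)  # 3 of 10 stop trials responded
        np.testing.assert_allclose(s.p_stop_by_ssd[[0, 4]], [1.0, 0.5])
        assert np.isnan(s.p_stop_by_ssd[1:4]).all()  # no trials at 250-350 ms
        np.testing.assert_allclose(
            s.q_correct, rt_quantiles(0.50 + 0.01 * np.arange(8))
        )
        np.testing.assert_allclose(s.q_error, rt_quantiles([0.58, 0.60, 0.62]))

    def test_row_order_invariance(self, reactive_design):
        t = _hand_table()
        shuffled = t.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a, b = summarize(t, reactive_design), summarize(shuffled, reactive_design)
        assert a.p_go == b.p_go
        np.testing.assert_allclose(a.q_correct, b.q_correct)
        np.testing.assert_allclose(a.p_stop_by_ssd, b.p_stop_by_ssd)

    def test_no_stop_responses_leaves_error_quantiles_absent(self, reactive_design):
        t = _hand_table()
        t.loc[t["trial_type"] == "stop", "response"] = 0
        t.loc[t["trial_type"] == "stop", "rt"] = np.nan
        s = summarize(t, reactive_design)
        assert s.q_error is None
        assert s.p_err == 0.0

    def test_all_go_answered_gives_unit_probability(self, reactive_design):
        t = _hand_table()
        t = t[t["trial_type"] == "go"].copy()
        t["response"] = 1
        t["rt"] = 0.5
        assert summarize(t, reactive_design).p_go == 1.0

    def test_proactive_pools_are_disjoint_and_exhaustive(self, proactive_design):
        rng = np.random.default_rng(0)
        rows = []
        for cue in proactive_design.cues:
            for _ in range(30):
                resp = int(rng.random() < 0.3 + 0.5 * cue)
                rows.append(
                    ("s0", f"p{int(cue*100)}", "proactive", "go", np.nan, cue,
                     resp, 0.45 + 0.05 * rng.random() if resp else np.nan)
                )
        t = pd.DataFrame(rows, columns=["subject", "condition", "task", "trial_type", "ssd", "cue", "response", "rt"])
        s = summarize(t, proactive_design)
        n_hi = t[(t["cue"] > 0.5) & (t["response"] == 1)].shape[0]
        n_lo = t[(t["cue"] < 0.5) & (t["response"] == 1)].shape[0]
        assert n_hi + n_lo == (t["response"] == 1).sum()  # default cues avoid 0.5
        assert s.q_hi is not None and s.q_lo is not None
        assert len(s.p_resp_by_cue) == 6

    def test_average_summaries_elementwise_mean(self, reactive_design):
        s1 = summarize(_hand_table(), reactive_design)
        t2 = _hand_table()
        t2["rt"] = t2["rt"] + 0.02
        s2 = summarize(t2, reactive_design)
        avg = average_summaries([s1, s2])
        np.testing.assert_allclose(avg.q_correct, (s1.q_correct + s2.q_correct) / 2)
        assert avg.p_go == pytest.approx(0.8)


class TestLogisticPse:
    def test_pse_arithmetic(self):
        assert LogisticFit(slope=-4.0, intercept=2.0).pse == pytest.approx(0.5)

    def test_recovers_generating_pse(self):
        rng = np.random.default_rng(11)
        lam, lam0 = 10.0, -3.0  # true PSE = 0.3
        x = np.tile(np.linspace(0, 1, 8), 250)  # n = 2000
        p = 1 / (1 + np.exp(-(lam * x + lam0)))
        y = (rng.random(x.size) < p).astype(float)
        fit = logistic_pse(x, y)
        assert fit.pse == pytest.approx(0.3, abs=0.02)

    def test_median_recovery_error_small_over_cohorts(self):
        rng = np.random.default_rng(5)
        errs = []
        x_levels = np.linspace(0, 1, 6)
        for _ in range(100):
            lam, lam0 = 8.0, -4.0  # PSE = 0.5
            p = 1 / (1 + np.exp(-(lam * x_levels + lam0)))
            counts = rng.binomial(60, p)
            fit = logistic_pse(x_levels, counts / 60, n=np.full(6, 60))
            errs.append(abs(fit.pse - 0.5))
        assert np.median(errs) < 0.02

    def test_constant_outcomes_rejected(self):
        with pytest.raises(ValueError):
            logistic_pse([0, 0.5, 1.0], [1.0, 1.0, 1.0])

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            logistic_pse([0.3, 0.3], [0, 1])

    def test_perfect_separation_flagged_not_fatal(self):
        x = np.array([0.0, 0.1, 0.2, 0.8, 0.9, 1.0])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        fit = logistic_pse(x, y)
        assert fit.separation_flagged
        assert 0.2 < fit.pse < 0.8
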