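"""Tests for weight construction, cost functions, and fit bookkeeping."""
import numpy as np
import pytest

from nestedrace.fitting import (
    FitConfig,
    FitResult,
    WeightSet,
    accuracy_weights,
    best_of_n,
    cost_proactive,
    cost_reactive,
    information_criteria,
    maritz_jarrett_se,
    quantile_weights,
)
from nestedrace.params import ProcessParams, TaskDesign
from nestedrace.stats import ObservedSummary


class TestMaritzJarrett:
    def test_matches_bootstrap_se_of_median(self):
        rng = np.random.default_rng(2024)
        x = rng.standard_normal(200)
        mj = maritz_jarrett_se(x, 0.5)
        boots = np.median(
            rng.choice(x, size=(10_000, x.size), replace=True), axis=1
        )
        assert mj == pytest.approx(boots.std(ddof=1), rel=0.15)

    def test_constant_sample_has_zero_se(self):
        assert maritz_jarrett_se(np.full(50, 1.7), 0.3) == 0.0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        x = rng.exponential(size=80)
        for c in (0.1, 3.0):
            assert maritz_jarrett_se(c * x, 0.7) == pytest.approx(
                c * maritz_jarrett_se(x, 0.7), rel=1e-9
            )

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            maritz_jarrett_se([1.0, 2.0, 3.0], 0.5)


class TestQuantileWeights:
    def test_median_se_ratio_arithmetic(self, monkeypatch):
        # SEs (2,1,1,1,2) -> weights (0.5,1,1,1,0.5) under median-of-SEs
        import nestedrace.fitting as F

        ses = iter([2.0, 1.0, 1.0, 1.0, 2.0])
        monkeypatch.setattr(F, "maritz_jarrett_se", lambda s, q: next(ses))
        np.testing.assert_allclose(
            F.quantile_weights(np.arange(20.0)), [0.5, 1, 1, 1, 0.5]
        )

    def test_identical_ses_give_unit_weights(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 0.05, 400)
        w = quantile_weights(x)
        assert np.all(w > 0)
        # real samples: roughly balanced, exactly scale-invariant
        np.testing.assert_allclose(quantile_weights(3.0 * x), w, rtol=1e-9)

    def test_degenerate_sample_capped(self):
        w = quantile_weights(np.full(50, 0.5))
        np.testing.assert_allclose(w, 1.0)


class TestAccuracyWeights:
    def test_mean_sd_ratio_arithmetic(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, size=(200, 3))
        mat = 0.5 + 0.01 * base * np.array([1.0, 1.0, 4.0])
        w = accuracy_weights(mat)
        assert w == pytest.approx([2.0, 2.0, 0.5], rel=0.05)

    def test_equal_sds_give_unit_weights(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(0.5, 0.1, size=(500, 4))
        np.testing.assert_allclose(accuracy_weights(mat), 1.0, rtol=0.1)

    def test_permuting_conditions_permutes_weights(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(0.5, 0.1, size=(40, 3)) * np.array([1, 2, 3])
        w = accuracy_weights(mat)
        perm = [2, 0, 1]
        np.testing.assert_allclose(accuracy_weights(mat[:, perm]), w[perm])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            accuracy_weights(np.array([[0.5, 0.6]]))


def _reactive_summary(**over):
    base = dict(
        kind="reactive",
        p_go=0.98,
        p_stop_by_ssd=np.array([0.9, 0.8, 0.6, 0.4, 0.2]),
        q_correct=np.array([0.50, 0.53, 0.56, 0.59, 0.62]),
        q_error=np.array([0.48, 0.51, 0.54, 0.57, 0.60]),
        p_corr=0.98,
        p_err=0.4,
    )
    base.update(over)
    return ObservedSummary(**base)


def _proactive_summary(**over):
    base = dict(
        kind="proactive",
        p_resp_by_cue=np.array([0.1, 0.25, 0.45, 0.6, 0.8, 0.9]),
        q_hi=np.array([0.50, 0.52, 0.53, 0.54, 0.55]),
        q_lo=np.array([0.51, 0.52, 0.54, 0.55, 0.55]),
        p_high=0.77,
        p_low=0.27,
    )
    base.update(over)
    return ObservedSummary(**base)


class TestCosts:
    def test_doubling_weights_doubles_reactive_cost(self, reactive_design):
        obs = {"pooled": _reactive_summary()}
        pred = {"pooled": _reactive_summary(p_go=0.95, p_err=0.4)}
        w1 = WeightSet.unit("reactive", reactive_design)
        w2 = WeightSet(
            kind="reactive", w_g=2.0, w_d=2 * w1.w_d, w_c=2 * w1.w_c, w_e=2 * w1.w_e
        )
        c1 = cost_reactive(obs, pred, w1)
        c2 = cost_reactive(obs, pred, w2)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_condition_set_mismatch_rejected(self, reactive_design):
        w = WeightSet.unit("reactive", reactive_design)
        with pytest.raises(ValueError):
            cost_reactive({"a": _reactive_summary()}, {"b": _reactive_summary()}, w)

    def test_proactive_multiplier_structure(self, proactive_design):
        w = WeightSet.unit("proactive", proactive_design)
        obs_none = _proactive_summary(p_high=0.0, p_low=0.0)
        pred = _proactive_summary(
            q_hi=np.array([0.4, 0.45, 0.5, 0.52, 0.54]),
            p_resp_by_cue=np.array([0.2, 0.25, 0.45, 0.6, 0.8, 0.9]),
        )
        # with no responses the cost reduces to the probability terms
        c = cost_proactive(obs_none, pred, w)
        assert c == pytest.approx(0.1**2, rel=1e-12)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightSet(kind="reactive", w_g=0.0)
        with pytest.raises(ValueError):
            WeightSet(kind="reactive", w_c=np.array([1, 1, -1, 1, 1.0]))


class TestInformationCriteria:
    def test_no_parameters_means_no_penalty(self):
        aic, bic = information_criteria(0.01, 0, 16)
        assert aic == bic == pytest.approx(16 * np.log(0.01 / 16))

    def test_gaussian_sse_convention_value(self):
        aic, bic = information_criteria(0.0028, 5, 16)
        assert aic == pytest.approx(16 * np.log(0.0028 / 16) + 10, rel=1e-12)
        assert aic == pytest.approx(-128.4, abs=0.05)
        assert bic == pytest.approx(16 * np.log(0.0028 / 16) + 5 * np.log(16), rel=1e-12)

    def test_ordering_invariant_to_shared_data_count(self):
        # same costs at two n values: the better model stays better
        a1, _ = information_criteria(0.002, 5, 16)
        a2, _ = information_criteria(0.004, 5, 16)
        b1, _ = information_criteria(0.002, 5, 32)
        b2, _ = information_criteria(0.004, 5, 32)
        assert (a1 < a2) == (b1 < b2)

    def test_zero_cost_sentinel(self):
        aic, bic = information_criteria(0.0, 3, 16)
        assert aic == float("-inf") and bic == float("-inf")

    def test_overparameterised_rejected(self):
        with pytest.raises(ValueError):
            information_criteria(0.01, 16, 16)


def _result(aic, cost, idx):
    return FitResult(
        model_kind="dpm", modulation="none",
        params_by_condition={"pooled": ProcessParams(a=0.5, tr=0.1, v_e=1.0)},
        cost=cost, k=5, n=16, aic=aic, bic=aic, seed=idx,
    )


class TestBestOfN:
    def test_single_result_returned(self):
        r = _result(-10, 0.01, 0)
        assert best_of_n([r]) is r

    def test_lowest_aic_wins(self):
        rs = [_result(-10, 0.01, 0), _result(-12, 0.02, 1), _result(-11, 0.005, 2)]
        assert best_of_n(rs).aic == -12

    def test_ties_broken_by_cost_then_index(self):
        rs = [_result(-12, 0.02, 0), _result(-12, 0.01, 1), _result(-12, 0.01, 2)]
        winner = best_of_n(rs)
        assert winner.cost == 0.01 and winner.seed == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_of_n([])


class TestFitConfig:
    def test_protocol_requires_three_restarts(self):
        with pytest.raises(ValueError):
            FitConfig(n_restarts=2)

    def test_basin_limits_must_be_positive(self):
        with pytest.raises(ValueError):
            FitConfig(basin_max_iter=0)
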