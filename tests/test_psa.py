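"""PSA and acceptability curves: sampling moments, unbiasedness, CEAC laws."""

import dataclasses

import numpy as np
import pytest

from sch_cea import (
    Arm,
    CostInputs,
    ModelConfig,
    base_case,
    build_arm_dists,
    ceac,
    draw_psa_inputs,
    nmb,
    run_psa,
)
from sch_cea.params import Moments, UtilizationParams


def _degenerate_calibration(published_calibration):
    """Same means, all SDs zero: every PSA draw equals the base case."""
    out = {}
    for arm, (u, traj) in published_calibration.items():
        zeroed = UtilizationParams(
            arm=arm,
            p_ed_week=Moments(u.p_ed_week.mean, 0.0),
            n_ed_given_any=Moments(u.n_ed_given_any.mean, 0.0),
            p_hosp_week=Moments(u.p_hosp_week.mean, 0.0),
            n_hosp_given_any=Moments(u.n_hosp_given_any.mean, 0.0),
            los_days=Moments(u.los_days.mean, 0.0),
        )
        out[arm] = (zeroed, traj)
    return out


def _degenerate_costs(cost_inputs):
    return dataclasses.replace(
        cost_inputs,
        c_ed_visit=Moments(cost_inputs.c_ed_visit.mean, 0.0),
        c_night=Moments(cost_inputs.c_night.mean, 0.0),
    )


class TestDraws:
    def test_zero_sd_draws_equal_means(self, published_calibration,
                                       cost_inputs):
        cal = _degenerate_calibration(published_calibration)
        dists = {a: build_arm_dists(u) for a, (u, _) in cal.items()}
        util, costs = draw_psa_inputs(
            dists, _degenerate_costs(cost_inputs), seed=1, size=5)
        u = published_calibration[Arm.NP_DSS][0]
        d = util[Arm.NP_DSS]
        assert np.all(d["p_ed"] == u.p_ed_week.mean)
        assert np.all(d["n_ed"] == u.n_ed_given_any.mean)
        assert np.all(d["los"] == u.los_days.mean)
        assert np.all(costs["c_night"] == cost_inputs.c_night.mean)

    def test_same_seed_identical(self, published_calibration, cost_inputs):
        dists = {a: build_arm_dists(u)
                 for a, (u, _) in published_calibration.items()}
        u1, c1 = draw_psa_inputs(dists, cost_inputs, seed=9, size=100)
        u2, c2 = draw_psa_inputs(dists, cost_inputs, seed=9, size=100)
        assert np.array_equal(c1["c_ed_visit"], c2["c_ed_visit"])
        for arm in u1:
            for key in u1[arm]:
                assert np.array_equal(u1[arm][key], u2[arm][key])

    def test_seed_required(self, published_calibration, cost_inputs):
        dists = {a: build_arm_dists(u)
                 for a, (u, _) in published_calibration.items()}
        with pytest.raises(ValueError, match="seed"):
            draw_psa_inputs(dists, cost_inputs, seed=None)

    def test_gamma_cost_sampling_moment(self, published_calibration,
                                        cost_inputs):
        """1e5 draws of the per-night cost recover its mean within 3 SE."""
        dists = {Arm.SCC: build_arm_dists(published_calibration[Arm.SCC][0])}
        _, costs = draw_psa_inputs(dists, cost_inputs, seed=21, size=100_000)
        x = costs["c_night"]
        assert abs(x.mean() - 3574.0) < 3 * 122.0 / np.sqrt(x.size)


class TestRunPsa:
    def test_degenerate_psa_equals_base_case(self, published_calibration,
                                             cost_inputs, model_config):
        cal = _degenerate_calibration(published_calibration)
        costs = _degenerate_costs(cost_inputs)
        cfg = model_config.with_(psa_outer=20)
        result = run_psa(cal, costs, cfg)
        det = {o.arm: o.total_cost for o in base_case(cal, costs, cfg)}
        for j, arm in enumerate(result.arms):
            assert np.allclose(result.costs[:, j], det[arm], rtol=0, atol=1e-9)

    def test_reproducible(self, published_calibration, cost_inputs,
                          model_config):
        cfg = model_config.with_(psa_outer=50)
        a = run_psa(published_calibration, cost_inputs, cfg)
        b = run_psa(published_calibration, cost_inputs, cfg)
        assert np.array_equal(a.costs, b.costs)
        assert a.config_hash == b.config_hash

    def test_mean_unbiased_vs_base_case(self, published_calibration,
                                        cost_inputs, model_config):
        cfg = model_config.with_(psa_outer=1000)
        result = run_psa(published_calibration, cost_inputs, cfg)
        det = {o.arm: o.total_cost
               for o in base_case(published_calibration, cost_inputs, cfg)}
        for o in result.mean_outcomes():
            assert abs(o.total_cost - det[o.arm]) < 3 * o.mc_se_cost

    def test_microsim_inner_agrees(self, published_calibration, cost_inputs):
        """The M-patient inner loop adds first-order noise around the same mean."""
        cfg = ModelConfig(seed=13, psa_outer=40, psa_inner=200)
        cal = {Arm.NP_DSS: published_calibration[Arm.NP_DSS]}
        closed = run_psa(cal, cost_inputs, cfg)
        micro = run_psa(cal, cost_inputs, cfg, microsim_inner=True)
        a, b = closed.mean_outcomes()[0], micro.mean_outcomes()[0]
        se = np.hypot(a.mc_se_cost, b.mc_se_cost)
        assert abs(a.total_cost - b.total_cost) < 4 * se


class TestNmb:
    def test_pure_cost_ranking_at_zero_wtp(self):
        assert nmb(500.0, 5.0, 0.0) == -500.0

    def test_published_row_arithmetic(self):
        assert nmb(18_200.0, 4.5, 1000.0) == pytest.approx(-12_700.0)

    def test_anchor_shift_cancels_in_differences(self):
        d1 = nmb(100.0, 4.0, 50.0, anchor=10.0) - nmb(80.0, 6.0, 50.0, anchor=10.0)
        d2 = nmb(100.0, 4.0, 50.0, anchor=12.0) - nmb(80.0, 6.0, 50.0, anchor=12.0)
        assert d1 == pytest.approx(d2)

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            nmb(100.0, 5.0, -1.0)


class TestCeac:
    @pytest.fixture()
    def degenerate_result(self, published_calibration, cost_inputs):
        cal = _degenerate_calibration(published_calibration)
        cfg = ModelConfig(seed=2, psa_outer=10)
        return run_psa(cal, _degenerate_costs(cost_inputs), cfg)

    def test_cheapest_arm_wins_at_zero_wtp(self, degenerate_result):
        curve = ceac(degenerate_result, [0.0])
        probs = dict(zip(curve.arms, curve.probabilities[0]))
        assert probs[Arm.NP_DSS] == pytest.approx(1.0)

    def test_best_effect_arm_wins_above_crossover(self, degenerate_result):
        curve = ceac(degenerate_result, [10_000.0, 20_000.0, 1e9])
        j = curve.arms.index(Arm.COMPLETE_SCH)
        assert np.all(curve.probabilities[:, j] == pytest.approx(1.0))

    def test_probabilities_normalized(self, published_calibration,
                                      cost_inputs, model_config):
        cfg = model_config.with_(psa_outer=200)
        result = run_psa(published_calibration, cost_inputs, cfg)
        curve = ceac(result, cfg.wtp_grid)
        assert np.allclose(curve.probabilities.sum(axis=1), 1.0)
        assert np.all((curve.probabilities >= 0)
                      & (curve.probabilities <= 1))

    def test_best_effect_acceptability_tends_to_one(self, published_calibration,
                                                    cost_inputs, model_config):
        """Effects are constant across draws, so as WTP grows the lowest-burden
        arm must win every draw."""
        cfg = model_config.with_(psa_outer=300)
        result = run_psa(published_calibration, cost_inputs, cfg)
        curve = ceac(result, [0.0, 1e7, 1e12])
        j = curve.arms.index(Arm.COMPLETE_SCH)
        assert curve.probabilities[-1, j] == pytest.approx(1.0)
        assert (curve.probabilities[1, j] >= curve.probabilities[0, j])

    def test_empty_grid_rejected(self, degenerate_result):
        with pytest.raises(ValueError):
            ceac(degenerate_result, [])

    def test_long_format_frame(self, degenerate_result):
        curve = ceac(degenerate_result, [0.0, 100.0])
        frame = curve.to_frame()
        assert list(frame.columns) == ["wtp", "arm", "probability"]
        assert len(frame) == 2 * len(curve.arms)
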