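"""Complex-spike conditioned pooling and manifold plasticity analyses."""

import numpy as np
import pandas as pd
import pytest

from vermis.cs_plasticity import (
    CSCondition,
    conditioned_manifold_comparison,
    cs_trial_mask,
    estimate_cs_on_direction,
    pool_simulated_error_trials,
    post_cs_velocity_change,
)


@pytest.fixture()
def toy_session():
    """Ten centrifugal trials with hand-placed CS times (ms from offset)."""
    trials = pd.DataFrame(
        dict(
            trial_index=np.arange(10),
            type="centrifugal",
            direction="right",
            pv=np.linspace(430, 520, 10),
            duration_ms=np.linspace(65, 55, 10),
            error_direction=["right", "left", "none", "right", "left",
                             "right", "none", "left", "right", "left"],
        )
    )
    cs = {
        "pcA": {0: np.array([60.0]), 3: np.array([100.0]), 5: np.array([139.9]),
                8: np.array([140.0])},       # 140 ms belongs to the late window
        "pcB": {1: np.array([70.0]), 4: np.array([90.0]), 7: np.array([55.0])},
    }
    cs_on = {"pcA": "right", "pcB": "left"}
    return trials, cs, cs_on


class TestWindows:
    def test_half_open_boundary(self, toy_session):
        trials, cs, _ = toy_session
        order = trials["trial_index"].to_numpy()
        early = cs_trial_mask(cs["pcA"], order, (50.0, 140.0))
        late = cs_trial_mask(cs["pcA"], order, (140.0, 250.0))
        assert early[5] and not late[5]        # 139.9 ms -> early
        assert late[8] and not early[8]        # 140.0 ms -> late
        assert not (early & late).any()


class TestCSOnEstimation:
    def test_zero_cs_unresolved(self, config):
        trials = pd.DataFrame(
            dict(trial_index=np.arange(40),
                 error_direction=["left", "right"] * 20)
        )
        cfg = config.replace(cs_min_trials_per_direction=10)
        assert estimate_cs_on_direction({}, trials, cfg) is None

    def test_recovery_on_generator(self, medium_session, config):
        from vermis.pipeline import _unit_rates

        _, bundle, _, truth = medium_session
        cf, _, ev = _unit_rates(bundle, config, "PC", 0.0)
        hits = [
            estimate_cs_on_direction(d["cs"], cf, config)
            == truth.cs_on_directions[uid]
            for uid, d in ev.items()
        ]
        assert np.mean(hits) >= 0.95

    def test_insufficient_trials_unresolved(self, config):
        trials = pd.DataFrame(dict(trial_index=[0, 1], error_direction=["left", "right"]))
        assert estimate_cs_on_direction({0: np.array([60.0])}, trials, config) is None


class TestPooling:
    def test_partition_per_unit(self, toy_session, config):
        trials, cs, cs_on = toy_session
        order = trials["trial_index"].to_numpy()
        for uid in cs_on:
            mask = cs_trial_mask(cs[uid], order, (50.0, 140.0))
            assert mask.sum() + (~mask).sum() == len(order)

    def test_toy_enumeration(self, toy_session, config):
        trials, cs, cs_on = toy_session
        cond = CSCondition("outward")  # rightward movement -> error vector right
        pools = pool_simulated_error_trials(cs_on, cs, trials, cond, config)
        # pcA (CS-ON right) takes its early-window CS trials {0, 3, 5}
        assert list(pools["pcA"][0]) == [0, 3, 5]
        assert list(pools["pcA"][1]) == [1, 4, 6]
        # pcB (CS-ON left) takes its no-CS trials
        assert list(pools["pcB"][0]) == [0, 2, 3, 5, 6, 8, 9]

    def test_last_trial_contributes_no_post(self, toy_session, config):
        trials, cs, cs_on = toy_session
        cs2 = dict(cs)
        cs2["pcA"] = {**cs["pcA"], 9: np.array([60.0])}
        pools = pool_simulated_error_trials(cs_on, cs2, trials,
                                            CSCondition("outward"), config)
        assert 9 in pools["pcA"][0]
        assert len(pools["pcA"][1]) == len(pools["pcA"][0]) - 1

    def test_none_condition_uses_no_cs_trials_for_all(self, toy_session, config):
        trials, cs, cs_on = toy_session
        pools = pool_simulated_error_trials(cs_on, cs, trials,
                                            CSCondition("none"), config)
        assert list(pools["pcA"][0]) == [1, 2, 4, 6, 7, 8, 9]
        assert list(pools["pcB"][0]) == [0, 2, 3, 5, 6, 8, 9]

    def test_unresolved_unit_dropped(self, toy_session, config):
        trials, cs, cs_on = toy_session
        pools = pool_simulated_error_trials(
            {**cs_on, "pcC": None}, {**cs, "pcC": {}}, trials,
            CSCondition("outward"), config,
        )
        assert "pcC" not in pools


class TestConditionedComparison:
    @pytest.fixture(scope="class")
    def rates_session(self, config):
        from vermis.pipeline import _unit_rates, _grid
        from vermis.synth import SessionConfig, generate_session

        cfg = SessionConfig(
            n_trials=200, seed=23, direction_schedule="centrifugal_only",
            n_mf_bt=0, n_mf_llb=0, n_mf_slb=0,
            n_pc_burst=4, n_pc_pause=3, n_pc_burst_pause=2, n_pc_pause_burst=1,
        )
        bundle, _, _ = generate_session(cfg, config, with_traces=False)
        cf, rates, ev = _unit_rates(bundle, config, "PC", config.ss_smoothing_sd_ms)
        return cf, rates, ev, _grid(config)

    def test_identical_pools_null(self, rates_session, config):
        """The same pool compared against itself: zero angle difference and
        chance-level one-sided p."""
        cf, rates, ev, grid = rates_session
        cs_on = {uid: estimate_cs_on_direction(d["cs"], cf, config)
                 for uid, d in ev.items()}
        cs_ev = {u: d["cs"] for u, d in ev.items()}
        cond = CSCondition("none")
        pools = pool_simulated_error_trials(cs_on, cs_ev, cf, cond, config)
        cfg = config.replace(min_pool_trials=20)
        comp = conditioned_manifold_comparison(
            rates, cf, {"none": pools, "outward": pools, "inward": pools},
            grid, cfg,
        )
        assert comp.angles["outward"] == pytest.approx(comp.angles["none"], abs=1e-9)
        for p in comp.tests["p"]:
            assert 0.4 < p < 0.6

    def test_angles_invariant_to_latent_rescaling(self, rates_session, config):
        """Multiplying all rates by a constant rescales sizes and speeds but
        leaves the normalized slope angles unchanged."""
        cf, rates, ev, grid = rates_session
        cs_on = {uid: estimate_cs_on_direction(d["cs"], cf, config)
                 for uid, d in ev.items()}
        cs_ev = {u: d["cs"] for u, d in ev.items()}
        pools = {
            name: pool_simulated_error_trials(cs_on, cs_ev, cf,
                                              CSCondition(name), config)
            for name in ("none", "outward", "inward")
        }
        cfg = config.replace(min_pool_trials=20)
        comp1 = conditioned_manifold_comparison(rates, cf, pools, grid, cfg)
        scaled = {u: 2.0 * r for u, r in rates.items()}
        comp2 = conditioned_manifold_comparison(scaled, cf, pools, grid, cfg)
        for k in comp1.angles:
            assert comp2.angles[k] == pytest.approx(comp1.angles[k], abs=1e-6)


class TestVelocityChange:
    def _velocities(self, trials):
        from vermis.synth import velocity_profile

        return {
            int(r.trial_index): np.pad(
                velocity_profile(r.pv, r.duration_ms, 15.0 * r.pv / 475.0), (0, 40)
            )[:80]
            for r in trials.itertuples()
        }

    def test_planted_pv_increase_detected(self, config):
        rng = np.random.default_rng(0)
        n = 60
        pv = rng.uniform(450, 500, n)
        trials = pd.DataFrame(dict(trial_index=np.arange(n), pv=pv,
                                   duration_ms=15000.0 / (0.62 * pv)))
        # post trials (odd) get +5% PV
        trials.loc[trials.trial_index % 2 == 1, "pv"] *= 1.05
        vel = self._velocities(trials)
        pools = {"u0": (np.arange(0, n, 2), np.arange(1, n, 2))}
        rep = post_cs_velocity_change(vel, trials, pools)
        assert rep["pv_change_pct"] == pytest.approx(5.0, abs=1.5)

    def test_planted_duration_decrease_detected(self, config):
        rng = np.random.default_rng(1)
        n = 60
        pv = rng.uniform(450, 500, n)
        trials = pd.DataFrame(dict(trial_index=np.arange(n), pv=pv,
                                   duration_ms=15000.0 / (0.62 * pv)))
        trials.loc[trials.trial_index % 2 == 1, "duration_ms"] *= 0.9
        vel = self._velocities(trials)
        pools = {"u0": (np.arange(0, n, 2), np.arange(1, n, 2))}
        rep = post_cs_velocity_change(vel, trials, pools)
        assert rep["duration_change_pct"] == pytest.approx(-10.0, abs=2.0)

    def test_null_differences_within_ci(self, config):
        rng = np.random.default_rng(2)
        n = 80
        pv = rng.uniform(460, 490, n)
        trials = pd.DataFrame(dict(trial_index=np.arange(n), pv=pv,
                                   duration_ms=15000.0 / (0.62 * pv)))
        vel = self._velocities(trials)
        pools = {"u0": (np.arange(0, n, 2), np.arange(1, n, 2))}
        rep = post_cs_velocity_change(vel, trials, pools)
        assert abs(rep["pv_change_pct"]) < 3.0
        assert (rep["p"] < 0.05).mean() < 0.2

    def test_too_few_pairs(self, config):
        with pytest.raises(ValueError):
            post_cs_velocity_change({}, pd.DataFrame(dict(trial_index=[0])), {})
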