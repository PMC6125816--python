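"""Synthetic cohort generation: task designs, race behavior, motion, BOLD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stopnet.hrf import double_gamma_hrf, event_regressor
from stopnet.simulate import (
    GroundTruthSpec,
    RaceParams,
    StaircaseConfig,
    component_timecourses,
    default_ground_truth,
    generate_cohort,
    generate_task_design,
    simulate_motion,
    simulate_race_behavior,
    synthesize_bold,
)
from stopnet.simulate.bold import epoch_labels


class TestTaskDesign:
    def test_default_composition(self, default_design):
        counts = default_design.counts()
        assert counts["Go"] == 360
        assert counts["Stop"] == 80
        assert counts["NoGo"] == 40

    def test_small_design_proportions(self):
        d = generate_task_design(7, 2, 1, n_sessions=1, seed=0)
        c = d.counts()
        assert (c["Go"], c["Stop"], c["NoGo"]) == (7, 2, 1)

    def test_deterministic_given_seed(self):
        a = generate_task_design(seed=3).trials
        b = generate_task_design(seed=3).trials
        pd.testing.assert_frame_equal(a, b)

    def test_onsets_strictly_increasing_within_session(self, default_design):
        for s in (1, 2):
            on = default_design.session(s)["onset"].to_numpy()
            assert np.all(np.diff(on) > 0)

    def test_counts_split_evenly_across_sessions(self, default_design):
        per = default_design.trials.groupby("session")["trial_type"].value_counts()
        for tt, total in (("Go", 360), ("Stop", 80), ("NoGo", 40)):
            assert per[1][tt] + per[2][tt] == total
            assert abs(per[1][tt] - per[2][tt]) <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_task_design(n_go=-1)

    @given(
        n_go=st.integers(0, 40),
        n_stop=st.integers(0, 15),
        n_nogo=st.integers(0, 10),
        n_sessions=st.integers(1, 3),
    )
    @settings(max_examples=25, deadline=None)
    def test_trial_count_conservation(self, n_go, n_stop, n_nogo, n_sessions):
        d = generate_task_design(n_go, n_stop, n_nogo, n_sessions, seed=1)
        c = d.counts()
        assert c.get("Go", 0) == n_go
        assert c.get("Stop", 0) == n_stop
        assert c.get("NoGo", 0) == n_nogo


class TestRaceModel:
    def test_deterministic_race_inequality(self):
        """Stop finishing at SSD + stop time before the go time cancels."""
        d = generate_task_design(0, 10, 0, 1, seed=0)
        params = RaceParams(
            go_rt_mu=500.0, go_rt_sigma=1e-6, go_rt_tau=1e-6,
            ssrt_mu=200.0, ssrt_sigma=1e-6,
            go_omission_p=0, go_error_p=0, trigger_failure_p=0,
        )
        stair = StaircaseConfig(initial_ssd_ms=250, min_ssd_ms=250, max_ssd_ms=250)
        beh = simulate_race_behavior(d, params, stair, seed=1)
        # stop finishes at 450 < 500 -> every trial is a successful stop
        assert (beh["category"] == "SuccStop").all()

    def test_trigger_failure_boundary(self):
        d = generate_task_design(0, 20, 0, 1, seed=0)
        params = RaceParams(trigger_failure_p=1.0, go_omission_p=0.0)
        beh = simulate_race_behavior(d, params, seed=2)
        assert beh["response"].all()

    def test_response_rate_increases_with_ssd(self):
        """Race consistency: p(respond|signal) grows with fixed SSD."""
        rates = []
        for ssd in (100.0, 300.0, 500.0):
            d = generate_task_design(0, 400, 0, 1, seed=4)
            stair = StaircaseConfig(initial_ssd_ms=ssd, min_ssd_ms=ssd, max_ssd_ms=ssd)
            beh = simulate_race_behavior(d, RaceParams(trigger_failure_p=0), stair, seed=5)
            rates.append(beh["response"].mean())
        assert rates[0] < rates[1] < rates[2]

    def test_categories_cover_all_trials(self, default_behavior):
        assert default_behavior["category"].notna().all()
        assert len(default_behavior) == 480

    def test_same_seed_reproduces(self, default_design):
        a = simulate_race_behavior(default_design, seed=9)
        b = simulate_race_behavior(default_design, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestMotion:
    def test_zero_severity_is_zero(self):
        m = simulate_motion(50, severity=0.0, seed=0)
        assert (m.to_numpy() == 0).all()

    def test_deterministic(self):
        pd.testing.assert_frame_equal(
            simulate_motion(40, seed=7), simulate_motion(40, seed=7)
        )

    def test_motion_increases_with_age_across_cohort(self):
        """Monte-Carlo: mean step magnitude correlates positively with age."""
        rng = np.random.default_rng(0)
        ages = rng.uniform(18, 88, 120)
        disp = []
        for i, age in enumerate(ages):
            m = simulate_motion(80, severity=1.0, age=age, seed=100 + i).to_numpy()
            disp.append(np.abs(np.diff(m[:, 0])).mean())
        assert np.corrcoef(ages, disp)[0, 1] > 0.3


def _two_comp_truth(base=0.0, mod=0.0, evoked=None, **kw):
    ev = evoked or {}
    amp = {
        "correctGo": ev.get("correctGo", np.zeros(2)),
        "correctNoGo": ev.get("correctNoGo", np.zeros(2)),
        "SuccStop": ev.get("SuccStop", np.zeros(2)),
        "UnsuccStop": ev.get("UnsuccStop", np.zeros(2)),
    }
    off = np.array([[0.0, 1.0], [1.0, 0.0]])
    return GroundTruthSpec(
        spatial_maps=np.eye(2),
        evoked_amplitudes=amp,
        base_coupling=base * off,
        coupling_modulation=mod * off,
        noise_sd=0.0,
        **kw,
    )


class TestBoldForwardModel:
    def test_single_event_traces_hrf(self):
        """Noise-free single Go event: voxel trace is the scaled HRF."""
        d = generate_task_design(1, 0, 0, 1, iti_s=10.0, jitter_s=0.0, seed=0)
        beh = simulate_race_behavior(
            d, RaceParams(go_omission_p=0, go_error_p=0), seed=0
        )
        truth = GroundTruthSpec(
            spatial_maps=np.array([[1.0, 0.5]]) / np.sqrt(1.25),
            evoked_amplitudes={"correctGo": np.array([2.0])},
            base_coupling=np.zeros((1, 1)),
            coupling_modulation=np.zeros((1, 1)),
            noise_sd=0.0,
        )
        truth0 = GroundTruthSpec(
            spatial_maps=truth.spatial_maps.copy(),
            evoked_amplitudes={"correctGo": np.array([0.0])},
            base_coupling=np.zeros((1, 1)),
            coupling_modulation=np.zeros((1, 1)),
            noise_sd=0.0,
        )
        tc = component_timecourses(d, beh, truth, 1, np.random.default_rng(0))
        tc0 = component_timecourses(d, beh, truth0, 1, np.random.default_rng(0))
        onset = beh["onset"].iloc[0]
        expected = 2.0 * event_regressor(
            np.array([onset]), d.n_volumes_per_session, d.tr_s
        )
        # identical intrinsic draws cancel: the difference is the pure evoked HRF
        np.testing.assert_allclose(tc[:, 0] - tc0[:, 0], expected, atol=1e-10)
        # and voxel data are the evoked trace scaled by the map weight
        data = (tc - tc0) @ truth.spatial_maps
        np.testing.assert_allclose(data[:, 1], expected * truth.spatial_maps[0, 1],
                                   atol=1e-10)

    def test_forward_model_linearity(self):
        """Doubling evoked amplitudes doubles the noise-free evoked signal."""
        d = generate_task_design(20, 5, 2, 1, seed=1)
        beh = simulate_race_behavior(d, seed=1)
        ev1 = {"correctGo": np.array([1.0, 0.3])}
        ev2 = {"correctGo": np.array([2.0, 0.6])}
        tc0 = component_timecourses(d, beh, _two_comp_truth(), 1, np.random.default_rng(3))
        tc1 = component_timecourses(d, beh, _two_comp_truth(evoked=ev1), 1, np.random.default_rng(3))
        tc2 = component_timecourses(d, beh, _two_comp_truth(evoked=ev2), 1, np.random.default_rng(3))
        # identical intrinsic draws cancel in the differences
        np.testing.assert_allclose(tc2 - tc0, 2.0 * (tc1 - tc0), atol=1e-10)

    def test_base_coupling_recovered_in_correlation(self):
        """Empirical TC correlation matches configured base coupling."""
        d = generate_task_design(0, 0, 0, 1, seed=2)
        # long no-task series: build explicit design of 12000 volumes
        truth = _two_comp_truth(base=0.6)
        beh = pd.DataFrame(
            {"trial_type": [], "onset": [], "session": [], "category": []}
        )
        from stopnet.simulate.design import TaskDesign

        d = TaskDesign(
            trials=pd.DataFrame(
                {"trial_type": [], "onset": [], "arrow_dir": [], "session": []}
            ),
            tr_s=2.0,
            n_volumes_per_session=12000,
        )
        rng = np.random.default_rng(8)
        tc = component_timecourses(d, beh, truth, 1, rng)
        r = np.corrcoef(tc[:, 0], tc[:, 1])[0, 1]
        assert abs(r - 0.6) < 0.03

    def test_modulation_raises_within_epoch_correlation(self):
        """Coupling during SuccStop epochs exceeds UnsuccStop epochs."""
        d = generate_task_design(100, 300, 20, 1, seed=3)
        beh = simulate_race_behavior(d, RaceParams(), seed=3)
        truth = _two_comp_truth(base=0.4, mod=0.4)
        rng = np.random.default_rng(9)
        tc = component_timecourses(d, beh, truth, 1, rng)
        lab = epoch_labels(beh, 1, d.n_volumes_per_session, d.tr_s, truth.epoch_window_s)
        r_succ = np.corrcoef(tc[lab == 1, 0], tc[lab == 1, 1])[0, 1]
        r_unsucc = np.corrcoef(tc[lab == 2, 0], tc[lab == 2, 1])[0, 1]
        assert r_succ > r_unsucc + 0.1

    def test_dimension_mismatch_raises(self, small_design):
        beh = simulate_race_behavior(small_design, seed=0)
        truth = _two_comp_truth()
        motion = {1: pd.DataFrame(np.zeros((3, 6)),
                                  columns=["trans_x", "trans_y", "trans_z",
                                           "rot_x", "rot_y", "rot_z"])}
        truth.motion_artifact_gain = 1.0
        with pytest.raises(ValueError):
            synthesize_bold(small_design, beh, truth, motion, seed=0)


class TestCohort:
    def test_ages_within_range_and_seeds_distinct(self):
        coh = generate_cohort(50, seed=1)
        ages = [s.age_years for s in coh.subjects]
        assert min(ages) >= 18 and max(ages) <= 88
        seeds = [s.seed for s in coh.subjects]
        assert len(set(seeds)) == len(seeds)

    def test_ssrt_ground_truth_correlates_with_age(self):
        coh = generate_cohort(150, seed=2)
        t = coh.table()
        assert np.corrcoef(t["age_years"], t["ssrt_true_ms"])[0, 1] > 0.2

    def test_zero_slopes_make_parameters_age_independent(self):
        truth = default_ground_truth(seed=0)
        truth.age_slopes = {k: 0.0 for k in truth.age_slopes}
        from stopnet.simulate import BehaviorLink

        link = BehaviorLink(ssrt_age_slope=0.0, go_rt_age_slope=0.0, moderation=0.0)
        coh = generate_cohort(200, truth=truth, link=link, seed=3)
        t = coh.table()
        r = np.corrcoef(t["age_years"], t["ssrt_true_ms"])[0, 1]
        assert abs(r) < 0.15

    def test_unit_norm_maps_invariant(self):
        truth = default_ground_truth(seed=4)
        np.testing.assert_allclose(
            np.linalg.norm(truth.spatial_maps, axis=1), 1.0, atol=1e-12
        )

    def test_hrf_shape(self):
        h = double_gamma_hrf()
        assert h.max() == pytest.approx(1.0)
        t_peak = np.argmax(h) * 0.1
        assert 4.5 <= t_peak <= 6.5
        assert h[int(16 / 0.1)] < 0  # undershoot
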