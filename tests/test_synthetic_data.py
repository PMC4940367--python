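"""Virtual-subject simulator: HRF, determinism, lateralization, closed loop."""

import numpy as np
import pytest

from nfloop import (
    SessionConfig,
    VirtualSubjectProfile,
    canonical_hrf,
    closed_loop_run,
    cohens_d,
    concentrations_to_od,
    intensities_to_od,
    od_to_concentrations,
    simulate_cohort,
    simulate_epoch_pair,
    simulate_session,
)
from nfloop import session_model as sm
from nfloop.signal_core import detect_motion_artifacts
from nfloop.synthetic_data import hrf_kernel, inject_motion_artifacts, simulate_channel


class TestHrf:
    def test_zero_at_onset(self):
        assert canonical_hrf(0.0) == 0.0

    def test_peak_between_five_and_seven_seconds(self):
        grid = np.arange(0, 32, 0.1)
        h = canonical_hrf(grid)
        assert 5.0 <= grid[np.argmax(h)] <= 7.0
        assert h.max() == pytest.approx(1.0)

    def test_net_positive_response(self):
        grid = np.arange(0, 32, 0.1)
        assert canonical_hrf(grid).sum() * 0.1 > 0

    def test_kernel_unit_sum(self):
        assert hrf_kernel(2.0).sum() == pytest.approx(1.0)


class TestSimulateChannel:
    def test_all_zero_profile_is_flat(self, config):
        profile = VirtualSubjectProfile(
            responder_gain=0, right_gain=0, view_gain=0, noise_sd=1e-12,
            drift_slope=0, mayer_amp=0, resp_amp=0)
        blocks = sm.build_block_schedule(config)
        rng = np.random.default_rng(0)
        noisy, clean = simulate_channel(profile, blocks, "left", rng)
        assert np.allclose(clean, 0.0)

    def test_left_exceeds_right_in_nf_window_expectation(self, config):
        """Monte-Carlo sign check of the programmed lateralization."""
        blocks = sm.build_block_schedule(config)
        wins = [sm.extract_epoch_window(b.nf, 7.0, config.fs) for b in blocks]
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            left, _ = simulate_channel(
                VirtualSubjectProfile(), blocks, "left", rng, config.fs)
            right, _ = simulate_channel(
                VirtualSubjectProfile(), blocks, "right", rng, config.fs)
            d = np.mean([left[i0:i1].mean() - right[i0:i1].mean()
                         for i0, i1 in wins])
            hits += d > 0
        assert hits >= 45

    def test_identical_seed_identical_series(self, config):
        blocks = sm.build_block_schedule(config)
        a, _ = simulate_channel(VirtualSubjectProfile(), blocks, "left",
                                np.random.default_rng(5))
        b, _ = simulate_channel(VirtualSubjectProfile(), blocks, "left",
                                np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestSimulateSession:
    def test_cohort_emits_all_blocks(self, config):
        profiles = [VirtualSubjectProfile(subject_id=f"s{i:02d}")
                    for i in range(17)]
        sessions = simulate_cohort(profiles, config, seed=0)
        n_blocks = sum(len(s.blocks) for s in sessions)
        assert n_blocks == 136
        assert all(len(s.ground_truth) == 8 for s in sessions)

    def test_session_seed_determinism(self, responder_profile):
        a = simulate_session(responder_profile, seed=7)
        b = simulate_session(responder_profile, seed=7)
        assert np.array_equal(a.series.hbo, b.series.hbo)
        assert a.markers.equals(b.markers)

    def test_ground_truth_d_matches_recovered_d(self, config):
        """Recovered standardized shift tracks the realized ground truth."""
        ds, dts = [], []
        for seed in range(12):
            s = simulate_session(VirtualSubjectProfile(), config, seed=seed)
            mon = config.montage
            asym = (s.series.hbo[:, mon.left_idx].mean(1)
                    - s.series.hbo[:, mon.right_idx].mean(1))
            for blk, t in zip(s.blocks, s.ground_truth):
                v0, v1 = sm.extract_epoch_window(blk.view, 7, 2, asym.size)
                f0, f1 = sm.extract_epoch_window(blk.nf, 7, 2, asym.size)
                ds.append(cohens_d(asym[v0:v1], asym[f0:f1]))
                dts.append(t.d_true)
        assert np.mean(ds) == pytest.approx(np.mean(dts), abs=0.15)

    def test_mbll_forward_inverse_recovers_simulated_hbo(self, config):
        """Synthesised raw intensities invert to the simulated HbO."""
        s = simulate_session(VirtualSubjectProfile(), config, seed=1)
        hbo = s.series.hbo[:200, :2]
        hbr = s.series.hbr[:200, :2]
        od = concentrations_to_od(hbo, hbr)
        i_ref = 2000.0
        intensities = i_ref * 10.0 ** (-od)
        od_back = intensities_to_od(intensities, i_ref)
        hbo2, hbr2 = od_to_concentrations(od_back)
        assert np.allclose(hbo2, hbo, atol=1e-6)
        assert np.allclose(hbr2, hbr, atol=1e-6)


class TestEpochPairGenerator:
    def test_programmed_effect_recovered_on_average(self):
        rng = np.random.default_rng(0)
        for d_true in (0.35, 1.0, 2.58):
            est = np.mean([cohens_d(*simulate_epoch_pair(d_true, 80, rng))
                           for _ in range(500)])
            assert est == pytest.approx(d_true, abs=0.1)

    def test_recovery_regression_slope_near_unity(self):
        rng = np.random.default_rng(4)
        d_true = rng.uniform(0.2, 3.0, 500)
        d_hat = np.array([cohens_d(*simulate_epoch_pair(d, 80, rng))
                          for d in d_true])
        slope = np.polyfit(d_true, d_hat, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)


class TestMotionArtifactInjection:
    def test_zero_rate_is_identity(self, rng):
        x = rng.normal(size=500)
        y, mask = inject_motion_artifacts(x, 2.0, 0.0, 5.0, rng)
        assert np.array_equal(x, y) and not mask.any()

    def test_smar_recall_on_large_events(self):
        """Detection sweep: SMAR recovers >= 90% of 10x-noise events."""
        noise_sd = 0.2
        flagged_events = total_events = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, noise_sd, 1200)
            y, truth = inject_motion_artifacts(
                x, 2.0, rate_per_min=1.0, magnitude=10 * noise_sd, rng=rng)
            mask, _ = detect_motion_artifacts(y, 2.0)
            # event-level recall: any overlap with the detected mask
            starts = np.flatnonzero(np.diff(truth.astype(int)) == 1)
            ends = np.flatnonzero(np.diff(truth.astype(int)) == -1)
            for s, e in zip(starts, ends):
                total_events += 1
                flagged_events += mask[s:e + 1].any()
        assert total_events > 10
        assert flagged_events / total_events >= 0.9

    def test_seeded_reproducibility(self):
        x = np.zeros(300)
        a = inject_motion_artifacts(x, 2.0, 2.0, 1.0,
                                    np.random.default_rng(3))
        b = inject_motion_artifacts(x, 2.0, 2.0, 1.0,
                                    np.random.default_rng(3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestClosedLoop:
    def test_strong_responder_succeeds_and_delights_agent(
            self, responder_profile):
        res = closed_loop_run(responder_profile, seed=3, n_boot=0)
        assert res.summary.n_success >= 1
        assert res.summary.respondent
        ids = {bid for tl in res.timelines.values()
               for bid in tl["behavior_id"]}
        assert ids & {"HighPos1", "HighPos2"}

    def test_non_respondent_receives_no_feedback(self, non_respondent_profile):
        res = closed_loop_run(non_respondent_profile, seed=11, n_boot=0,
                              render_timelines=False)
        assert not res.crossed_threshold
        assert not res.summary.received_feedback
        assert res.summary.n_success == 0

    def test_scale_invariance_of_success_decisions(self, config):
        """Doubling gains and noise together leaves t and d unchanged."""
        p1 = VirtualSubjectProfile(drift_slope=0, mayer_amp=0, resp_amp=0)
        p2 = VirtualSubjectProfile(
            responder_gain=2 * p1.responder_gain,
            right_gain=2 * p1.right_gain, view_gain=2 * p1.view_gain,
            noise_sd=2 * p1.noise_sd, drift_slope=0, mayer_amp=0, resp_amp=0)
        a = closed_loop_run(p1, config, seed=5, n_boot=0,
                            render_timelines=False)
        b = closed_loop_run(p2, config, seed=5, n_boot=0,
                            render_timelines=False)
        for ra, rb in zip(a.block_results, b.block_results):
            assert ra.success == rb.success
            assert ra.d == pytest.approx(rb.d, rel=1e-6)

    def test_gain_schedule_modulates_block_success(self, config):
        """A strategy shift (gain off in half the blocks) shows up per block."""
        profile = VirtualSubjectProfile(view_gain=0.0, drift_slope=0.0)
        schedule = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0]
        res = closed_loop_run(profile, config, seed=2, n_boot=0,
                              render_timelines=False,
                              gain_schedule=schedule)
        on = [r.d for r, s in zip(res.block_results, schedule) if s == 1.0]
        off = [r.d for r, s in zip(res.block_results, schedule) if s == 0.0]
        assert min(on) > max(off)
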