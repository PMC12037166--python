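"""Generator tests: block layout, HRF, forward model, events, behavior."""

import math

import numpy as np
import pytest

from reactivate.core import REPLAY, TASK, ConfigurationError
from reactivate.synthetic import (
    GroundTruth,
    SimConfig,
    canonical_hrf,
    coupling_for_target_r,
    make_block_events,
    make_patterns,
    simulate_behavior,
    simulate_cohort,
    simulate_rest_session,
    simulate_subject,
    simulate_task_session,
    window_overlap_fraction,
)


class TestBlockLayout:
    def test_default_layout(self):
        events = make_block_events(SimConfig())
        assert len(events) == 20
        assert events.conditions[::2] == (TASK,) * 10
        assert events.conditions[1::2] == (REPLAY,) * 10
        assert events.onsets_s[0] == 9.0  # after the initial fixation
        assert events.onsets_s[1] == 27.0  # 18 s later: 12 s block + 6 s gap
        assert np.all(events.durations_s == 12.0)
        assert np.all(events.onsets_s % 3.0 == 0.0)  # TR-aligned

    def test_single_pair_no_gap(self):
        cfg = SimConfig(blocks_per_condition=1, inter_block_gap_s=0.0)
        events = make_block_events(cfg)
        onset0 = events.onsets_s[0]
        assert list(events.onsets_s) == [onset0, onset0 + 12.0]
        assert events.conditions == (TASK, REPLAY)

    def test_design_overflow_raises(self):
        with pytest.raises(ConfigurationError, match="design overflow"):
            make_block_events(SimConfig(task_scans=60))

    def test_non_tr_aligned_layout_rejected(self):
        with pytest.raises(ConfigurationError, match="multiple of tr_s"):
            SimConfig(inter_block_gap_s=5.0).validate()


class TestCanonicalHrf:
    def test_shape_and_peak(self):
        h = canonical_hrf(3.0)
        assert h.shape == (11,)  # 0..30 s inclusive at TR 3
        assert np.argmax(h) == 2  # peak at the 6 s sample
        assert h.max() == pytest.approx(1.0)

    def test_matches_double_gamma_formula(self):
        # independent oracle: direct gamma-density evaluation via math.gamma
        def gpdf(t, shape):
            if t <= 0:
                return 0.0
            return t ** (shape - 1) * math.exp(-t) / math.gamma(shape)

        tr = 2.0
        t = np.arange(int(32 // tr) + 1) * tr
        expected = np.array([gpdf(x, 6.0) - gpdf(x, 16.0) / 6.0 for x in t])
        expected /= expected.max()
        np.testing.assert_allclose(canonical_hrf(tr), expected, atol=1e-12)

    def test_invalid_tr(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestTaskForwardModel:
    def test_zero_everything_gives_zero_series(self, small_config):
        cfg = SimConfig(
            n_voxels=30, pattern_amplitude=0.0, drift_amplitude=0.0, noise_sd=0.0
        )
        truth = GroundTruth(*make_patterns(cfg, np.random.default_rng(0)), 0.0)
        events = make_block_events(cfg)
        ts = simulate_task_session(cfg, truth, events, 0)
        assert np.all(ts.data == 0.0)

    def test_projection_recovers_convolved_boxcar(self):
        # noiseless, driftless: series @ pattern_task == scale * (hrf * boxcar)
        from reactivate.synthetic import _pattern_scale, condition_regressor

        cfg = SimConfig(n_voxels=50, noise_sd=0.0, drift_amplitude=0.0)
        truth = GroundTruth(*make_patterns(cfg, np.random.default_rng(1)), 0.0)
        events = make_block_events(cfg)
        ts = simulate_task_session(cfg, truth, events, 0)
        reg = condition_regressor(events, TASK, cfg.task_scans, cfg.tr_s)
        proj = ts.data @ truth.pattern_task
        np.testing.assert_allclose(proj, _pattern_scale(cfg) * reg, atol=1e-10)

    def test_seed_determinism(self, small_config):
        truth = GroundTruth(*make_patterns(small_config, np.random.default_rng(2)), 0.0)
        events = make_block_events(small_config)
        a = simulate_task_session(small_config, truth, events, 7)
        b = simulate_task_session(small_config, truth, events, 7)
        c = simulate_task_session(small_config, truth, events, 8)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)


class TestPatterns:
    def test_unit_norm_and_orthogonal(self, rng):
        cfg = SimConfig(n_voxels=100)
        p_task, p_replay = make_patterns(cfg, rng)
        assert np.linalg.norm(p_task) == pytest.approx(1.0)
        assert np.linalg.norm(p_replay) == pytest.approx(1.0)
        assert p_task @ p_replay == pytest.approx(0.0, abs=1e-12)

    def test_configured_correlation(self, rng):
        cfg = SimConfig(n_voxels=100, pattern_correlation=0.4)
        p_task, p_replay = make_patterns(cfg, rng)
        assert p_task @ p_replay == pytest.approx(0.4, abs=1e-12)

    def test_sparse_support(self, rng):
        cfg = SimConfig(n_voxels=200, responsive_fraction=0.1)
        p_task, _ = make_patterns(cfg, rng)
        assert np.count_nonzero(p_task) == cfg.n_responsive == 20


class TestRestSession:
    def test_zero_events_pure_baseline(self, small_config, rng):
        truth = GroundTruth(*make_patterns(small_config, rng), 0.0)
        ts, onsets = simulate_rest_session(small_config, truth, 0, 0)
        assert onsets.size == 0
        assert ts.n_volumes == small_config.rest_scans

    def test_event_overlaps_seven_windows(self):
        # one 4-volume event interior to the run: 4 + 4 - 1 overlapping windows
        frac = window_overlap_fraction([50], event_len=4, n_volumes=119)
        assert frac == pytest.approx(7 / 116)

    def test_onsets_nonoverlapping_many_seeds(self, small_config, rng):
        truth = GroundTruth(*make_patterns(small_config, rng), 0.0)
        L = small_config.event_len_volumes
        n_ret = small_config.retained_rest_volumes
        for seed in range(1000):
            _, onsets = simulate_rest_session(small_config, truth, 10, seed)
            assert onsets.size == 10
            assert onsets.min() >= 0
            assert onsets.max() + L <= n_ret
            assert np.all(np.diff(np.sort(onsets)) >= L)

    def test_infeasible_event_count(self, small_config, rng):
        truth = GroundTruth(*make_patterns(small_config, rng), 0.0)
        with pytest.raises(ConfigurationError):
            simulate_rest_session(small_config, truth, 40, 0)

    def test_overlap_fraction_matches_bruteforce(self, rng):
        for _ in range(50):
            n_vol = int(rng.integers(10, 120))
            wl = int(rng.integers(2, 6))
            n_ev = int(rng.integers(0, 5))
            ev_len = int(rng.integers(1, 6))
            onsets = rng.integers(0, max(1, n_vol - ev_len), size=n_ev)
            # brute force: enumerate windows and volumes
            hits = 0
            starts = list(range(0, n_vol - wl + 1))
            for s in starts:
                win = set(range(s, s + wl))
                if any(win & set(range(o, o + ev_len)) for o in onsets):
                    hits += 1
            expected = hits / len(starts) if starts else 0.0
            got = window_overlap_fraction(onsets, ev_len, n_vol, window_len=wl)
            assert got == pytest.approx(expected)


class TestBehavior:
    def test_exact_recovery_without_noise(self):
        cfg = SimConfig(behavior_noise_sd=0.0, behavior_coupling=1.0)
        errors = simulate_behavior(cfg, true_fraction_increase_pp=7.5, seed=0)
        improvement = errors[:3].mean() - errors[3]
        assert improvement - cfg.behavior_session4_decrement == pytest.approx(7.5)

    def test_all_positive(self):
        cfg = SimConfig(behavior_baseline_mean=5.0, behavior_coupling=2.0)
        errors = simulate_behavior(cfg, 40.0, seed=3)
        assert np.all(errors > 0.0)

    def test_zero_coupling_uncorrelated(self, rng):
        cfg = SimConfig(behavior_coupling=0.0)
        df = rng.normal(10, 4, size=400)
        imp = np.array(
            [
                simulate_behavior(cfg, d, seed)[:3].mean()
                - simulate_behavior(cfg, d, seed)[3]
                for seed, d in enumerate(df)
            ]
        )
        assert abs(np.corrcoef(df, imp)[0, 1]) < 0.15

    def test_population_correlation_monte_carlo(self, rng):
        # coupling chosen for population R=0.6; sample R over a large cohort
        sd_df = 4.0
        cfg = SimConfig(
            behavior_coupling=coupling_for_target_r(0.6, sd_df, 2.0),
            behavior_noise_sd=2.0,
        )
        df = rng.normal(10.0, sd_df, size=200)
        imp = np.array(
            [
                simulate_behavior(cfg, d, 5000 + i)[:3].mean()
                - simulate_behavior(cfg, d, 5000 + i)[3]
                for i, d in enumerate(df)
            ]
        )
        r = np.corrcoef(df, imp)[0, 1]
        assert abs(r - 0.6) < 0.15


class TestCohort:
    def test_bit_identical_for_same_master_seed(self, small_config):
        a = simulate_cohort(small_config, 3, seed=11)
        b = simulate_cohort(small_config, 3, seed=11)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.rest_post.data, sb.rest_post.data)
            np.testing.assert_array_equal(sa.behavior, sb.behavior)

    def test_minimum_size(self, small_config):
        with pytest.raises(ValueError):
            simulate_cohort(small_config, 1, seed=0)

    def test_subjects_noise_mutually_uncorrelated(self):
        from reactivate.preprocess import discard_initial

        # isolate the stochastic part: no condition signal, no shared drift;
        # concatenate all task sessions so the bound is meaningful for
        # autocorrelated noise (chance |r| ~ 0.04 at T ~ 700)
        cfg = SimConfig(n_voxels=30, pattern_amplitude=0.0, drift_amplitude=0.0)
        subjects = simulate_cohort(cfg, 5, seed=13)
        series = [
            np.concatenate(
                [discard_initial(sess).data[:, 0] for sess, _ in s.task_sessions]
            )
            for s in subjects
        ]
        corrs = [
            abs(np.corrcoef(series[i], series[j])[0, 1])
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        assert np.mean(corrs) < 0.05

    def test_truth_bookkeeping(self, small_subject, small_config):
        truth = small_subject.truth
        expected = window_overlap_fraction(
            truth.rest_event_onsets["post"],
            small_config.event_len_volumes,
            small_config.retained_rest_volumes,
        )
        assert truth.true_reactivation_fraction["post"] == pytest.approx(expected)
        assert truth.true_reactivation_fraction["pre"] == 0.0
        assert small_subject.behavior.shape == (4,)
        assert np.all(small_subject.behavior > 0)
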