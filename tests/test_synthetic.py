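"""The synthetic cohort generator: determinism, calibration, group structure."""

import numpy as np
import pytest

from kinemap.imaging import session_to_images
from kinemap.signal_core import decompose_series
from kinemap.synthetic import (
    SimConfig,
    group_params,
    simulate_cohort,
    simulate_participant,
)


class TestSimulateParticipant:
    def test_quiescent_limit_pure_gravity_single_pixel_images(self):
        cfg = SimConfig(session_hours=0.05, noise_sd_g=0.0,
                        control_burst_rate_per_min=0.0, adhd_burst_rate_per_min=0.0)
        series = simulate_participant("control", cfg, seed=3)
        # unit-norm gravity drift only
        assert np.allclose(np.linalg.norm(series.a, axis=1), 1.0, atol=1e-9)
        stack = session_to_images(series)
        assert len(stack) > 0
        # every image: single set pixel at (1, 1) up to tiny drift leakage
        assert (stack.pixels.sum(axis=(1, 2)) == 1).mean() > 0.9
        assert (stack.pixels[:, 0, 0] == 1).all()

    def test_fixed_seed_byte_identical(self):
        cfg = SimConfig(session_hours=0.02)
        s1 = simulate_participant("adhd_nonmed", cfg, seed=11)
        s2 = simulate_participant("adhd_nonmed", cfg, seed=11)
        assert s1.a.tobytes() == s2.a.tobytes()
        assert s1.t.tobytes() == s2.t.tobytes()

    def test_resting_magnitude_near_one_g(self):
        cfg = SimConfig(session_hours=0.1, control_burst_rate_per_min=0.0,
                        adhd_burst_rate_per_min=0.0)
        series = simulate_participant("control", cfg, seed=5)
        assert np.mean(np.linalg.norm(series.a, axis=1)) == pytest.approx(1.0, abs=0.02)

    def test_burst_amplitude_calibration_monte_carlo(self):
        """Empirical peak mean over 1000 generator bursts sits within 3 SE of the
        configured log-normal mean (generator honesty)."""
        from kinemap.synthetic import sample_burst

        cfg = SimConfig(burst_peak_log_sd=0.35)
        _, median = group_params("adhd_nonmed", cfg)
        rng = np.random.default_rng(7)
        draws = [sample_burst(rng, cfg, median) for _ in range(1000)]
        peaks = np.array([d[0] for d in draws])
        taus = np.array([d[2] for d in draws])
        expected_mean = median * np.exp(cfg.burst_peak_log_sd**2 / 2)
        se = peaks.std(ddof=1) / np.sqrt(len(peaks))
        assert abs(peaks.mean() - expected_mean) < 3 * se
        lo, hi = cfg.burst_decay_s
        assert abs(taus.mean() - (lo + hi) / 2) < 3 * taus.std(ddof=1) / np.sqrt(len(taus))

    def test_group_intensity_ordering(self):
        """ADHD-like sessions carry more high-intensity movement than controls."""
        cfg = SimConfig(session_hours=0.2, effect_size=1.0)
        adhd = simulate_participant("adhd_nonmed", cfg, seed=1)
        ctrl = simulate_participant("control", cfg, seed=1)
        am_a = decompose_series(adhd)
        am_c = decompose_series(ctrl)
        v_a, v_c = am_a.valid, am_c.valid
        mag_a = np.linalg.norm(am_a.a_m[v_a], axis=1)
        mag_c = np.linalg.norm(am_c.a_m[v_c], axis=1)
        assert mag_a.mean() > mag_c.mean()
        # high-intensity region occupancy differs markedly
        assert (mag_a > 1.0).mean() > 5 * max((mag_c > 1.0).mean(), 1e-6)


class TestGroupParams:
    def test_effect_zero_groups_identical(self):
        cfg = SimConfig(effect_size=0.0)
        assert group_params("adhd_nonmed", cfg) == group_params("control", cfg)

    def test_effect_one_full_contrast(self):
        cfg = SimConfig(effect_size=1.0)
        rate, peak = group_params("adhd_nonmed", cfg)
        assert rate == cfg.adhd_burst_rate_per_min
        assert peak == pytest.approx(cfg.adhd_burst_peak_g)

    def test_medicated_between_groups(self):
        cfg = SimConfig(effect_size=1.0, medicated_shift=0.6)
        r_c, p_c = group_params("control", cfg)
        r_m, p_m = group_params("adhd_med", cfg)
        r_a, p_a = group_params("adhd_nonmed", cfg)
        assert r_c < r_m < r_a
        assert p_c < p_m < p_a

    def test_effect_size_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(effect_size=1.5)


class TestSimulateCohort:
    def test_structure_and_pairing_bijection(self):
        cfg = SimConfig(n_pairs=3, n_medicated=1, session_hours=0.01, sites=("wrist",))
        cohort = simulate_cohort(cfg)
        assert len(cohort.participants) == 8
        adhd_pairs = sorted(p.pair_id for p in cohort.participants
                            if p.group != "control")
        ctrl_pairs = sorted(p.pair_id for p in cohort.participants
                            if p.group == "control")
        assert adhd_pairs == ctrl_pairs
        ids = [p.participant_id for p in cohort.participants]
        assert len(set(ids)) == len(ids)

    def test_snap_scores_respect_diagnostic_cut(self):
        cohort = simulate_cohort(SimConfig(n_pairs=4, n_medicated=2,
                                           session_hours=0.01, sites=("wrist",)))
        for p in cohort.participants:
            if p.group == "control":
                assert p.snap_score < 1.44
            else:
                assert p.snap_score >= 1.44

    def test_master_seed_determinism_and_extendability(self):
        small = simulate_cohort(SimConfig(n_pairs=2, session_hours=0.01,
                                          sites=("wrist",), seed=9))
        again = simulate_cohort(SimConfig(n_pairs=2, session_hours=0.01,
                                          sites=("wrist",), seed=9))
        for p, q in zip(small.participants, again.participants):
            assert p.series["wrist"].a.tobytes() == q.series["wrist"].a.tobytes()
        bigger = simulate_cohort(SimConfig(n_pairs=3, session_hours=0.01,
                                           sites=("wrist",), seed=9))
        for p, q in zip(small.participants, bigger.participants):
            assert p.series["wrist"].a.tobytes() == q.series["wrist"].a.tobytes()

    def test_null_effect_mean_movement_calibration(self):
        """At effect 0, group mean |a_m| t-tests stay null in >= 18/20 replicates."""
        from kinemap.subject_inference import two_sample_ttest

        non_sig = 0
        for rep in range(20):
            cfg = SimConfig(n_pairs=4, session_hours=0.05, sites=("wrist",),
                            effect_size=0.0, seed=1000 + rep)
            cohort = simulate_cohort(cfg)
            means = {"adhd_nonmed": [], "control": []}
            for p in cohort.participants:
                dec = decompose_series(p.series["wrist"])
                means[p.group].append(
                    float(np.linalg.norm(dec.a_m[dec.valid], axis=1).mean()))
            _, p_val = two_sample_ttest(means["adhd_nonmed"], means["control"])
            non_sig += p_val >= 0.05
        assert non_sig >= 18

    def test_full_effect_mean_movement_power(self):
        """At effect 1, the same test is significant in >= 19/20 replicates."""
        from kinemap.subject_inference import two_sample_ttest

        sig = 0
        for rep in range(20):
            cfg = SimConfig(n_pairs=4, session_hours=0.05, sites=("wrist",),
                            effect_size=1.0, seed=2000 + rep)
            cohort = simulate_cohort(cfg)
            means = {"adhd_nonmed": [], "control": []}
            for p in cohort.participants:
                dec = decompose_series(p.series["wrist"])
                means[p.group].append(
                    float(np.linalg.norm(dec.a_m[dec.valid], axis=1).mean()))
            _, p_val = two_sample_ttest(means["adhd_nonmed"], means["control"])
            sig += p_val < 0.05
        assert sig >= 19

    def test_group_difference_survives_rotation_of_one_group(self):
        """The contrast is kinematic, not orientational: rotating one group's
        raw data leaves its images unchanged, so classification cannot rest on
        sensor placement."""
        from conftest import random_rotation
        from kinemap.signal_core import AccelSeries

        cfg = SimConfig(n_pairs=2, session_hours=0.05, sites=("wrist",), seed=4)
        cohort = simulate_cohort(cfg)
        rng = np.random.default_rng(0)
        r = random_rotation(rng)
        for p in cohort.participants:
            if p.group != "control":
                continue
            s = p.series["wrist"]
            rotated = AccelSeries(s.participant_id, s.sensor_site, s.sample_rate_hz,
                                  s.t, s.a @ r.T)
            assert np.array_equal(session_to_images(s).pixels,
                                  session_to_images(rotated).pixels)
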