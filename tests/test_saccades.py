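"""Velocity estimation, threshold detection, SRT extraction, inclusion rules."""

import numpy as np
import pytest

from srtpipe.saccades import (
    DetectionConfig,
    GazeTrace,
    TrialRecord,
    apply_inclusion,
    detect_saccades,
    detection_threshold,
    estimate_velocity,
    extract_srt,
)
from srtpipe.synthetic_data import GazeSimConfig, generate_gaze_trace

DT = 2.0


def make_trace(x, y=None):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return GazeTrace(t_ms=np.arange(len(x)) * DT, x_dva=x, y_dva=y)


def synthetic_trial(trial_id=0, fix_off=1000.0, srt=250.0, ecc=5.0, seed=0,
                    flash=False, **gaze_kwargs):
    row = {
        "trial_id": trial_id,
        "fix_off_ms": fix_off,
        "true_srt_ms": srt,
        "target_x_dva": ecc,
        "target_y_dva": 0.0,
    }
    cfg = GazeSimConfig(**gaze_kwargs) if gaze_kwargs else GazeSimConfig()
    trace, truth = generate_gaze_trace(row, np.random.default_rng(seed), cfg)
    rec = TrialRecord(
        trial_id=trial_id,
        task="Step",
        flash_present=flash,
        eccentricity=ecc,
        group="Equal",
        fixation_offset_ms=fix_off,
        flash_onset_ms=fix_off + 100.0 if flash else None,
        target_center=(ecc, 0.0),
    )
    return trace, truth, rec


class TestVelocity:
    def test_constant_position_gives_zero(self):
        v = estimate_velocity(make_trace(np.full(50, 3.0)))
        assert np.all(v[2:-2] == 0.0)
        assert np.all(np.isnan(v[:2])) and np.all(np.isnan(v[-2:]))

    def test_linear_ramp_is_exact(self):
        t_s = np.arange(100) * DT / 1000.0
        v = estimate_velocity(make_trace(10.0 * t_s))
        assert np.allclose(v[2:-2, 0], 10.0, atol=1e-9)

    def test_sinusoid_matches_analytic_derivative(self):
        # 5 Hz, far below the 250 Hz Nyquist limit
        t_s = np.arange(500) * DT / 1000.0
        omega = 2 * np.pi * 5.0
        v = estimate_velocity(make_trace(2.0 * np.sin(omega * t_s)))
        expected = 2.0 * omega * np.cos(omega * t_s)
        err = np.abs(v[2:-2, 0] - expected[2:-2])
        assert np.max(err) < 0.02 * 2.0 * omega

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_velocity(make_trace(np.zeros(3)))


class TestThreshold:
    def test_matches_median_estimator_on_gaussian_noise(self):
        """For Gaussian velocity noise the median spread is 0.6745 * sd."""
        rng = np.random.default_rng(0)
        v = rng.normal(0.0, 20.0, (10000, 2))
        eta_x, eta_y = detection_threshold(v, lam=10.0)
        expected = 10.0 * 0.674489 * 20.0
        assert eta_x == pytest.approx(expected, rel=0.05)
        assert eta_y == pytest.approx(expected, rel=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0.0, 5.0, (500, 2))
        base = detection_threshold(v, 10.0)
        scaled = detection_threshold(3.0 * v, 10.0)
        assert scaled[0] == pytest.approx(3.0 * base[0], rel=1e-9)

    def test_constant_velocity_degenerate(self):
        with pytest.raises(ValueError):
            detection_threshold(np.full((100, 2), 7.0), 10.0)


class TestDetection:
    def test_single_injected_saccade_recovered(self):
        trace, truth, _ = synthetic_trial(srt=250.0, ecc=5.0, seed=2)
        events = detect_saccades(trace)
        assert len(events) == 1
        assert abs(events[0].onset_ms - truth["true_onset_ms"]) <= 4.0
        assert events[0].amplitude_dva == pytest.approx(5.0, abs=1.0)

    def test_pure_fixation_no_events(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            t = np.arange(0, 1500, DT)
            tr = GazeTrace(t, rng.normal(0, 0.05, len(t)), rng.normal(0, 0.05, len(t)))
            hits += len(detect_saccades(tr)) > 0
        assert hits <= 5

    def test_two_saccades_in_order(self):
        """Two 300 ms-separated injected movements yield two ordered events."""
        rng = np.random.default_rng(4)
        t = np.arange(0, 1600, DT)
        x = np.zeros_like(t)
        for onset, start, stop in ((600.0, 0.0, 4.0), (900.0, 4.0, 8.0)):
            u = np.clip((t - onset) / 30.0, 0.0, 1.0)
            x += (stop - start) * (10 * u**3 - 15 * u**4 + 6 * u**5)
        x += rng.normal(0, 0.05, len(t))
        y = rng.normal(0, 0.05, len(t))
        events = detect_saccades(GazeTrace(t, x, y))
        assert len(events) == 2
        assert events[0].onset_ms < events[1].onset_ms
        assert abs(events[0].onset_ms - 600.0) <= 6.0
        assert abs(events[1].onset_ms - 900.0) <= 6.0

    def test_offset_invariance(self):
        trace, _, _ = synthetic_trial(seed=5)
        shifted = GazeTrace(trace.t_ms, trace.x_dva + 7.0, trace.y_dva - 3.0)
        a = detect_saccades(trace)
        b = detect_saccades(shifted)
        assert [e.onset_ms for e in a] == [e.onset_ms for e in b]


class TestSrtAndInclusion:
    def test_srt_is_onset_minus_fixation_offset(self):
        trace, truth, rec = synthetic_trial(fix_off=1000.0, srt=250.0, seed=6)
        rec = extract_srt(detect_saccades(trace), rec)
        assert rec.srt_ms == pytest.approx(truth["true_srt_ms"], abs=4.0)

    def test_no_saccade_after_offset(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 1500, DT)
        tr = GazeTrace(t, rng.normal(0, 0.05, len(t)), rng.normal(0, 0.05, len(t)))
        rec = TrialRecord(0, "Step", False, 5.0, "Equal", 1000.0, (5.0, 0.0))
        rec = extract_srt(detect_saccades(tr), rec)
        assert rec.srt_ms is None
        rec = apply_inclusion(rec)
        assert not rec.included and rec.exclusion_reason == "no_saccade"

    def test_pre_offset_saccade_ignored(self):
        """A saccade before fixation offset must not define the SRT."""
        rng = np.random.default_rng(8)
        t = np.arange(0, 2000, DT)
        x = np.zeros_like(t)
        for onset, start, stop in ((500.0, 0.0, 3.0), (1250.0, 3.0, 8.0)):
            u = np.clip((t - onset) / 30.0, 0.0, 1.0)
            x += (stop - start) * (10 * u**3 - 15 * u**4 + 6 * u**5)
        x += rng.normal(0, 0.05, len(t))
        tr = GazeTrace(t, x, rng.normal(0, 0.05, len(t)))
        rec = TrialRecord(0, "Step", False, 8.0, "Equal", 1000.0, (8.0, 0.0))
        rec = extract_srt(detect_saccades(tr), rec)
        assert rec.srt_ms == pytest.approx(250.0, abs=6.0)

    @pytest.mark.parametrize(
        "srt, err, flash, reason",
        [
            (80.0, 0.2, False, "srt_below_100"),
            (520.0, 0.2, False, "srt_above_500"),
            (250.0, 1.5, False, "landing_error"),
            (150.0, 0.2, True, "post_flash_window"),
            (250.0, 0.5, False, None),
        ],
    )
    def test_inclusion_rules_in_order(self, srt, err, flash, reason):
        rec = TrialRecord(
            0, "Delayed", flash, 5.0, "Equal", 1000.0, (5.0, 0.0),
            flash_onset_ms=1100.0 if flash else None,
        )
        rec.srt_ms = srt
        rec.saccade_onset_ms = 1000.0 + srt
        rec.landing_error_dva = err
        rec = apply_inclusion(rec)
        assert rec.exclusion_reason == reason
        assert rec.included == (reason is None)

    def test_flash_trial_outside_window_included(self):
        rec = TrialRecord(
            0, "Delayed", True, 5.0, "Equal", 1000.0, (5.0, 0.0), flash_onset_ms=1100.0
        )
        rec.srt_ms = 350.0  # onset at 1350, flash window ends at 1200
        rec.saccade_onset_ms = 1350.0
        rec.landing_error_dva = 0.3
        assert apply_inclusion(rec).included

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectionConfig(lam=0.0)
        with pytest.raises(ValueError):
            DetectionConfig(min_duration=0)
        with pytest.raises(ValueError):
            TrialRecord(0, "Step", True, 5.0, "Equal", 1000.0, (5.0, 0.0))
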