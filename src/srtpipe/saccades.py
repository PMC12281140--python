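"""Velocity-threshold saccade detection, SRT extraction, and trial inclusion.

Detection follows the Engbert-Kliegl scheme: per-sample 2-D velocity from a
5-sample symmetric difference, a per-axis threshold eta = lambda * sigma
where sigma is a median-based velocity spread estimate, and a saccade
wherever the elliptic criterion (vx/eta_x)^2 + (vy/eta_y)^2 > 1 is sustained
for a minimum number of samples.  SRT is the interval from fixation-dot
offset to the onset of the first subsequent saccade.

Trial inclusion mirrors the behavioural task rules: a response saccade must
exist, its SRT must lie in [100, 500) ms, it must land within 1.0 dva of the
target centre, and (in flash trials) its onset must not fall within 100 ms
after the flash.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GazeTrace",
    "SaccadeEvent",
    "TrialRecord",
    "DetectionConfig",
    "estimate_velocity",
    "detection_threshold",
    "detect_saccades",
    "extract_srt",
    "apply_inclusion",
    "process_trial",
    "SAMPLE_INTERVAL_MS",
]

SAMPLE_INTERVAL_MS = 2.0  # 500 Hz recording

# Inclusion-rule constants, ms / dva
MIN_SRT_MS = 100.0
MAX_SRT_MS = 500.0
TARGET_WINDOW_DVA = 1.0
POST_FLASH_EXCLUSION_MS = 100.0


@dataclass
class GazeTrace:
    """Uniformly sampled 500 Hz 2-D eye-position record (t in ms, x/y in dva)."""

    t_ms: np.ndarray
    x_dva: np.ndarray
    y_dva: np.ndarray
    eye: str = "right"

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_dva = np.asarray(self.x_dva, dtype=float)
        self.y_dva = np.asarray(self.y_dva, dtype=float)
        if not (len(self.t_ms) == len(self.x_dva) == len(self.y_dva)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_ms) >= 2:
            dt = np.diff(self.t_ms)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
                raise ValueError("timestamps must increase with a constant step")

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0]) if len(self.t_ms) > 1 else SAMPLE_INTERVAL_MS

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude_dva: float
    peak_velocity: float  # dva/s
    landing: tuple[float, float]  # (x, y) dva at the offset sample

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")


@dataclass
class TrialRecord:
    """One trial's events plus derived SRT and inclusion status."""

    trial_id: int
    task: str  # "Step" | "Delayed"
    flash_present: bool
    eccentricity: float
    group: str  # "Equal" | "Scaled"
    fixation_offset_ms: float
    target_center: tuple[float, float]
    contrast_level: str | None = None
    flash_onset_ms: float | None = None
    srt_ms: float | None = None
    saccade_onset_ms: float | None = None
    landing_error_dva: float | None = None
    included: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.flash_present != (self.flash_onset_ms is not None):
            raise ValueError("flash_onset_ms must be present iff flash_present")


@dataclass(frozen=True)
class DetectionConfig:
    lam: float = 10.0            # threshold multiplier lambda
    min_duration: int = 3        # samples (6 ms at 500 Hz)
    velocity_window: int = 5     # samples of the symmetric difference
    merge_gap: int = 2           # runs separated by < merge_gap samples merge
    eye: str = "right"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.velocity_window != 5:
            raise ValueError("only the 5-sample symmetric difference is supported")


def estimate_velocity(trace: GazeTrace, window: int = 5) -> np.ndarray:
    """Per-sample 2-D velocity in dva/s; boundary samples are NaN.

    v_n = (p_{n+2} + p_{n+1} - p_{n-1} - p_{n-2}) / (6 * dt).
    """
    if window != 5:
        raise ValueError("only the 5-sample symmetric difference is supported")
    n = len(trace)
    if n < window:
        raise ValueError(f"trace too short ({n} < {window}) for velocity estimation")
    dt_s = trace.dt_ms / 1000.0
    v = np.full((n, 2), np.nan)
    for k, p in enumerate((trace.x_dva, trace.y_dva)):
        v[2:-2, k] = (p[4:] + p[3:-1] - p[1:-3] - p[:-4]) / (6.0 * dt_s)
    return v


def detection_threshold(velocities: np.ndarray, lam: float = 10.0) -> tuple[float, float]:
    """Per-axis threshold eta = lambda * sqrt(median(v^2) - median(v)^2)."""
    v = velocities[~np.isnan(velocities[:, 0])]
    if len(v) < 10:
        raise ValueError("need at least 10 defined velocity samples")
    out = []
    for k in range(2):
        spread_sq = float(np.median(v[:, k] ** 2) - np.median(v[:, k]) ** 2)
        if spread_sq <= 1e-12:
            raise ValueError("degenerate velocity spread (constant-velocity trace)")
        out.append(lam * np.sqrt(spread_sq))
    return out[0], out[1]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/end (inclusive) indices of True runs."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def detect_saccades(trace: GazeTrace, config: DetectionConfig = DetectionConfig()) -> list[SaccadeEvent]:
    """Detect saccades with the 2-D elliptic velocity criterion.

    Supra-threshold runs separated by fewer than ``merge_gap`` samples are
    merged, then runs shorter than ``min_duration`` samples are dropped.
    """
    v = estimate_velocity(trace, config.velocity_window)
    eta_x, eta_y = detection_threshold(v, config.lam)
    crit = (v[:, 0] / eta_x) ** 2 + (v[:, 1] / eta_y) ** 2 > 1.0
    crit &= ~np.isnan(v[:, 0])

    runs = _runs(crit)
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < config.merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    speed = np.hypot(v[:, 0], v[:, 1])
    events = []
    for s, e in merged:
        if e - s + 1 < config.min_duration:
            continue
        dx = trace.x_dva[e] - trace.x_dva[s]
        dy = trace.y_dva[e] - trace.y_dva[s]
        events.append(
            SaccadeEvent(
                onset_ms=float(trace.t_ms[s]),
                offset_ms=float(trace.t_ms[e]),
                amplitude_dva=float(np.hypot(dx, dy)),
                peak_velocity=float(np.nanmax(speed[s : e + 1])),
                landing=(float(trace.x_dva[e]), float(trace.y_dva[e])),
            )
        )
    return events


def extract_srt(events: list[SaccadeEvent], trial: TrialRecord) -> TrialRecord:
    """SRT = onset of the first saccade after fixation offset, minus the offset.

    Returns an updated record; absence of a response saccade leaves srt_ms
    as None (the trial is excluded later).
    """
    t0 = trial.fixation_offset_ms
    response = next((ev for ev in events if ev.onset_ms > t0), None)
    if response is None:
        return replace(trial, srt_ms=None, saccade_onset_ms=None, landing_error_dva=None)
    err = float(
        np.hypot(
            response.landing[0] - trial.target_center[0],
            response.landing[1] - trial.target_center[1],
        )
    )
    return replace(
        trial,
        srt_ms=float(response.onset_ms - t0),
        saccade_onset_ms=float(response.onset_ms),
        landing_error_dva=err,
    )


def apply_inclusion(trial: TrialRecord, landing_error: float | None = None) -> TrialRecord:
    """Apply the behavioural inclusion rules; record the first failed rule.

    Rules, in order: a response saccade exists; SRT in [100, 500) ms; landing
    within 1.0 dva of the target centre; in flash trials, saccade onset not
    within (flash_onset, flash_onset + 100] ms.
    """
    err = trial.landing_error_dva if landing_error is None else landing_error
    reason = None
    if trial.srt_ms is None:
        reason = "no_saccade"
    elif trial.srt_ms < MIN_SRT_MS:
        reason = "srt_below_100"
    elif trial.srt_ms >= MAX_SRT_MS:
        reason = "srt_above_500"
    elif err is not None and err > TARGET_WINDOW_DVA:
        reason = "landing_error"
    elif trial.flash_present and trial.flash_onset_ms is not None:
        onset = (
            trial.saccade_onset_ms
            if trial.saccade_onset_ms is not None
            else trial.fixation_offset_ms + trial.srt_ms
        )
        if trial.flash_onset_ms < onset <= trial.flash_onset_ms + POST_FLASH_EXCLUSION_MS:
            reason = "post_flash_window"
    return replace(trial, included=reason is None, exclusion_reason=reason)


def process_trial(
    trace: GazeTrace,
    trial: TrialRecord,
    config: DetectionConfig = DetectionConfig(),
) -> TrialRecord:
    """Detect, extract SRT, and apply inclusion in one pass."""
    events = detect_saccades(trace, config)
    return apply_inclusion(extract_srt(events, trial))
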