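"""Synthetic trial tables and gaze traces with known ground truth.

The generator emulates the behavioural tasks: a Step task (fixation offset
and target onset in the same frame) and a Delayed task (target on for
800-1500 ms before the fixation-offset "Go" signal, with an optional
task-irrelevant foveal flash ~100 ms after Go on half the trials).  Targets
sit at {2,3,4,5,6,8,10} dva on the right horizontal meridian in Equal
(fixed 0.1 dva) and Scaled (extent-matched) versions.

SRTs are drawn from ex-Gaussians whose mode and FWHM follow linear trends
in eccentricity — the effect structure the analysis is designed to detect —
with a per-group slope and an additive flash delay.  Gaze traces are built
on top at 500 Hz: Gaussian fixational jitter, a minimum-jerk saccade
launched at fixation offset + true SRT whose duration follows a main
sequence (20 ms + 2 ms/dva), and a landing point scattered around the
target.  SRT-level and gaze-level generation are decoupled so statistical
tests can skip trace synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import exgauss
from .exgauss import ExGaussParams
from .saccades import SAMPLE_INTERVAL_MS, GazeTrace
from .sc_map import ScalingSpec, scaled_diameter

__all__ = [
    "ExperimentDesign",
    "GenerativeSRTModel",
    "solve_exgauss_params",
    "generate_srt_dataset",
    "generate_gaze_trace",
    "generate_gaze_dataset",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "trial_id",
    "task",
    "flash",
    "ecc_dva",
    "group",
    "contrast",
    "fix_off_ms",
    "flash_on_ms",
    "target_x_dva",
    "target_y_dva",
    "target_diam_dva",
]

EQUAL_DIAMETER_DVA = 0.1


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial structure of one task, with the experiment's timing ranges (ms)."""

    task: str = "Step"
    eccentricities: tuple[float, ...] = (2, 3, 4, 5, 6, 8, 10)
    groups: tuple[str, ...] = ("Equal", "Scaled")
    trials_per_condition: int = 250
    flash_proportion: float = 0.5  # Delayed task only
    step_fixation_range: tuple[float, float] = (800.0, 1500.0)
    delayed_fixation_range: tuple[float, float] = (800.0, 1000.0)
    target_duration_range: tuple[float, float] = (800.0, 1500.0)
    flash_onset_delay: float = 100.0
    flash_duration: float = 30.0
    max_srt: float = 500.0

    def __post_init__(self) -> None:
        if self.task not in ("Step", "Delayed"):
            raise ValueError("task must be 'Step' or 'Delayed'")
        if not 0.0 <= self.flash_proportion <= 1.0:
            raise ValueError("flash_proportion must be in [0, 1]")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")


@dataclass(frozen=True)
class GenerativeSRTModel:
    """Linear-in-eccentricity ex-Gaussian SRT structure.

    mode = base_mode + slope_group * (ecc - 2) [+ flash_delay];
    fwhm = base_fwhm + fwhm_slope * (ecc - 2).
    """

    base_mode: float = 160.0
    slope_equal: float = 5.0
    slope_scaled: float = 0.0
    flash_delay: float = 30.0
    base_fwhm: float = 60.0
    fwhm_slope: float = 2.0
    tau_sigma_ratio: float = 0.8

    def __post_init__(self) -> None:
        if self.base_mode <= 100:
            raise ValueError("base_mode must exceed 100 ms")
        if self.base_fwhm <= 0 or self.tau_sigma_ratio <= 0:
            raise ValueError("widths and ratio must be positive")

    def condition_targets(self, ecc: float, group: str, flash: bool) -> tuple[float, float]:
        slope = self.slope_scaled if group == "Scaled" else self.slope_equal
        m = self.base_mode + slope * (ecc - 2.0) + (self.flash_delay if flash else 0.0)
        f = self.base_fwhm + self.fwhm_slope * (ecc - 2.0)
        return m, f


def solve_exgauss_params(
    target_mode: float, target_fwhm: float, tau_sigma_ratio: float = 0.8
) -> ExGaussParams:
    """Ex-Gaussian parameters with the requested mode and FWHM at fixed tau/sigma.

    At fixed ratio r = tau/sigma, both mode - mu and FWHM scale linearly
    with sigma, so sigma follows from one reference evaluation at sigma = 1
    and mu is then shifted to place the mode.
    """
    if target_fwhm <= 0 or tau_sigma_ratio <= 0:
        raise ValueError("target_fwhm and ratio must be positive")
    unit = ExGaussParams(mu=0.0, sigma=1.0, tau=tau_sigma_ratio)
    unit_mode = exgauss.mode(unit)
    unit_fwhm = exgauss.fwhm(unit, _mode=unit_mode)
    sigma = target_fwhm / unit_fwhm
    mu = target_mode - sigma * unit_mode
    return ExGaussParams(mu=mu, sigma=sigma, tau=tau_sigma_ratio * sigma)


def generate_srt_dataset(
    design: ExperimentDesign = ExperimentDesign(),
    model: GenerativeSRTModel = GenerativeSRTModel(),
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Trial table with ground-truth SRTs drawn per condition.

    Columns: the trial-events schema plus ``true_srt_ms``.  Scaled target
    diameters follow the 2-dp stimulus table, Equal targets are 0.1 dva.
    Reproducible: the same seed yields an identical table.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    scaled = {e: scaled_diameter(e, ScalingSpec(rounding=2)) for e in design.eccentricities}
    flash_states = [False]
    if design.task == "Delayed" and design.flash_proportion > 0:
        flash_states = [False, True]

    rows = []
    trial_id = 0
    for ecc in design.eccentricities:
        for group in design.groups:
            for flash in flash_states:
                n = design.trials_per_condition
                if len(flash_states) == 2:
                    frac = design.flash_proportion if flash else 1.0 - design.flash_proportion
                    n = int(round(design.trials_per_condition * frac))
                if n == 0:
                    continue
                m, f = model.condition_targets(ecc, group, flash)
                params = solve_exgauss_params(m, f, model.tau_sigma_ratio)
                srts = exgauss.sample(params, n, rng)
                if design.task == "Step":
                    fix_off = rng.uniform(*design.step_fixation_range, n)
                else:
                    fix_off = rng.uniform(*design.delayed_fixation_range, n) + rng.uniform(
                        *design.target_duration_range, n
                    )
                for i in range(n):
                    rows.append(
                        {
                            "trial_id": trial_id,
                            "task": design.task,
                            "flash": flash,
                            "ecc_dva": float(ecc),
                            "group": group,
                            "contrast": np.nan,
                            "fix_off_ms": float(fix_off[i]),
                            "flash_on_ms": float(fix_off[i] + design.flash_onset_delay)
                            if flash
                            else np.nan,
                            "target_x_dva": float(ecc),
                            "target_y_dva": 0.0,
                            "target_diam_dva": scaled[ecc] if group == "Scaled" else EQUAL_DIAMETER_DVA,
                            "true_srt_ms": float(srts[i]),
                        }
                    )
                    trial_id += 1
    return pd.DataFrame(rows)


def _min_jerk(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on normalized time s in [0, 1]."""
    return 10.0 * s**3 - 15.0 * s**4 + 6.0 * s**5


@dataclass(frozen=True)
class GazeSimConfig:
    fixation_noise_sd: float = 0.05       # dva, per-sample white jitter
    landing_scatter_sd: float = 0.3       # dva, per-axis landing scatter
    duration_intercept_ms: float = 15.0   # main sequence: 15 ms + 2 ms/dva
    duration_slope_ms_per_dva: float = 2.0
    post_landing_ms: float = 200.0


def generate_gaze_trace(
    trial: dict | pd.Series,
    rng: np.random.Generator | int,
    config: GazeSimConfig = GazeSimConfig(),
) -> tuple[GazeTrace, dict]:
    """500 Hz gaze trace for one trial with a scheduled ground-truth saccade.

    The eye fixates (0, 0) with Gaussian jitter, launches a minimum-jerk
    saccade at fixation offset + true SRT toward a scattered landing point,
    then holds there.  Returns the trace and the ground truth
    (true SRT, landing point).  Flash events live in the events table only;
    they leave no gaze artifact.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fix_off = float(trial["fix_off_ms"])
    srt = float(trial["true_srt_ms"])
    if not np.isfinite(srt) or srt < 0:
        raise ValueError("trial needs a nonnegative ground-truth SRT")
    tx, ty = float(trial["target_x_dva"]), float(trial["target_y_dva"])
    land = (
        tx + rng.normal(0.0, config.landing_scatter_sd),
        ty + rng.normal(0.0, config.landing_scatter_sd),
    )
    amp = float(np.hypot(*land))
    dur = config.duration_intercept_ms + config.duration_slope_ms_per_dva * amp
    # the sampled eye can only start moving on the sample grid: snap the
    # scheduled onset to the next sample and report that as trace-level truth
    onset = SAMPLE_INTERVAL_MS * np.ceil((fix_off + srt) / SAMPLE_INTERVAL_MS)
    total = onset + dur + config.post_landing_ms
    t = np.arange(0.0, total, SAMPLE_INTERVAL_MS)

    x = np.zeros_like(t)
    y = np.zeros_like(t)
    moving = (t >= onset) & (t < onset + dur)
    s = _min_jerk((t[moving] - onset) / dur)
    x[moving] = land[0] * s
    y[moving] = land[1] * s
    after = t >= onset + dur
    x[after] = land[0]
    y[after] = land[1]
    x += rng.normal(0.0, config.fixation_noise_sd, len(t))
    y += rng.normal(0.0, config.fixation_noise_sd, len(t))

    trace = GazeTrace(t_ms=t, x_dva=x, y_dva=y)
    truth = {
        "trial_id": int(trial["trial_id"]),
        "true_srt_ms": float(onset - fix_off),
        "scheduled_srt_ms": srt,
        "true_onset_ms": float(onset),
        "true_landing_x": land[0],
        "true_landing_y": land[1],
    }
    return trace, truth


def generate_gaze_dataset(
    trials: pd.DataFrame,
    seed: int | np.random.SeedSequence = 0,
    config: GazeSimConfig = GazeSimConfig(),
) -> tuple[dict[int, GazeTrace], pd.DataFrame]:
    """Gaze traces for every trial in a table; per-trial seeded, reproducible."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(trials))
    traces: dict[int, GazeTrace] = {}
    truths = []
    for child, (_, trial) in zip(children, trials.iterrows()):
        trace, truth = generate_gaze_trace(trial, np.random.default_rng(child), config)
        traces[int(trial["trial_id"])] = trace
        truths.append(truth)
    return traces, pd.DataFrame(truths)
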