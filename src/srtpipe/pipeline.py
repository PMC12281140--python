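"""End-to-end orchestration: simulate -> detect -> include -> fit -> regress.

The pipeline ties the stages together under a single seeded configuration:
synthetic trial tables (and optionally gaze traces) are generated per
subject and task, SRTs are extracted by the velocity-threshold detector (or
taken from the SRT-level generator when gaze simulation is switched off),
the inclusion rules are applied, ex-Gaussians are fitted per condition, and
mode/FWHM are regressed on eccentricity with permutation p-values and
trial-level bootstrap CIs — separately per task and flash status, with a
fixed-effect aggregate when several subjects are simulated.

All tabular I/O is CSV with documented headers; a run report serializes to
a CSV set plus a JSON summary carrying seed and config provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference
from .inference import FixedEffectResult, RegressionResult, fixed_effect
from .saccades import (
    DetectionConfig,
    GazeTrace,
    TrialRecord,
    apply_inclusion,
    process_trial,
)
from .synthetic_data import (
    TRIAL_COLUMNS,
    ExperimentDesign,
    GazeSimConfig,
    GenerativeSRTModel,
    generate_gaze_dataset,
    generate_srt_dataset,
)

__all__ = [
    "AnalysisConfig",
    "RunReport",
    "run_full_analysis",
    "detect_srts",
    "read_trials",
    "write_trials",
    "read_gaze",
    "write_gaze",
    "write_report",
]

GAZE_COLUMNS = ["trial_id", "t_ms", "x_dva", "y_dva", "eye"]


@dataclass
class AnalysisConfig:
    tasks: tuple[str, ...] = ("Step", "Delayed")
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    model: GenerativeSRTModel = field(default_factory=GenerativeSRTModel)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    gaze: GazeSimConfig = field(default_factory=GazeSimConfig)
    simulate_gaze: bool = True
    n_subjects: int = 1
    n_perm: int = 1000
    n_boot: int = 1000
    ci_level: float = 95.0
    run_bootstrap: bool = True
    min_fit_n: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("design", ExperimentDesign),
            ("model", GenerativeSRTModel),
            ("detection", DetectionConfig),
            ("gaze", GazeSimConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        for key in ("tasks",):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tasks"] = list(self.tasks)
        for sub in ("design", "model", "detection", "gaze"):
            for k, v in list(d[sub].items()):
                if isinstance(v, tuple):
                    d[sub][k] = list(v)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    condition_summaries: pd.DataFrame
    regressions: pd.DataFrame
    fixed_effects: pd.DataFrame | None
    trials: pd.DataFrame
    provenance: dict


# ---------------------------------------------------------------- file I/O

def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TRIAL_COLUMNS, f"trial table {path}")
    bad = df.index[df["ecc_dva"] <= 0]
    if len(bad):
        raise ValueError(f"trial table {path}: nonpositive ecc_dva at row(s) {bad.tolist()[:5]}")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, TRIAL_COLUMNS, "trial table")
    df.to_csv(path, index=False)


def read_gaze(path: str | Path) -> dict[int, GazeTrace]:
    df = pd.read_csv(path)
    _require(df, GAZE_COLUMNS, f"gaze table {path}")
    traces = {}
    for tid, grp in df.groupby("trial_id", sort=True):
        traces[int(tid)] = GazeTrace(
            t_ms=grp["t_ms"].to_numpy(),
            x_dva=grp["x_dva"].to_numpy(),
            y_dva=grp["y_dva"].to_numpy(),
            eye=str(grp["eye"].iloc[0]),
        )
    return traces


def write_gaze(traces: dict[int, GazeTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "trial_id": tid,
                "t_ms": tr.t_ms,
                "x_dva": tr.x_dva,
                "y_dva": tr.y_dva,
                "eye": tr.eye,
            }
        )
        for tid, tr in sorted(traces.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ------------------------------------------------------------- detection

def _record_from_row(row: pd.Series) -> TrialRecord:
    flash = bool(row["flash"])
    return TrialRecord(
        trial_id=int(row["trial_id"]),
        task=str(row["task"]),
        flash_present=flash,
        eccentricity=float(row["ecc_dva"]),
        group=str(row["group"]),
        fixation_offset_ms=float(row["fix_off_ms"]),
        flash_onset_ms=float(row["flash_on_ms"]) if flash else None,
        target_center=(float(row["target_x_dva"]), float(row["target_y_dva"])),
    )


def detect_srts(
    trials: pd.DataFrame,
    traces: dict[int, GazeTrace],
    detection: DetectionConfig = DetectionConfig(),
) -> pd.DataFrame:
    """Run detection + inclusion on every trial; returns the table augmented
    with srt_ms, landing_error_dva, included, exclusion_reason."""
    out = trials.copy()
    srt, err, inc, reason = [], [], [], []
    for _, row in trials.iterrows():
        rec = process_trial(traces[int(row["trial_id"])], _record_from_row(row), detection)
        srt.append(rec.srt_ms)
        err.append(rec.landing_error_dva)
        inc.append(rec.included)
        reason.append(rec.exclusion_reason)
    out["srt_ms"] = srt
    out["landing_error_dva"] = err
    out["included"] = inc
    out["exclusion_reason"] = reason
    return out


def _include_from_ground_truth(trials: pd.DataFrame) -> pd.DataFrame:
    """SRT-level inclusion when gaze simulation is skipped (landing not modelled)."""
    out = trials.copy()
    inc, reason = [], []
    for _, row in trials.iterrows():
        rec = _record_from_row(row)
        rec.srt_ms = float(row["true_srt_ms"])
        rec.saccade_onset_ms = rec.fixation_offset_ms + rec.srt_ms
        rec = apply_inclusion(rec, landing_error=0.0)
        inc.append(rec.included)
        reason.append(rec.exclusion_reason)
    out["srt_ms"] = out["true_srt_ms"]
    out["included"] = inc
    out["exclusion_reason"] = reason
    return out


# ---------------------------------------------------------------- full run

def _analysis_cells(trials: pd.DataFrame):
    for (task, flash), cell in trials.groupby(["task", "flash"], sort=True):
        yield task, bool(flash), cell


def run_full_analysis(config: AnalysisConfig = AnalysisConfig()) -> RunReport:
    """Simulate, detect, include, fit, and regress under one seed."""
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    analysis_rng = np.random.default_rng(root.spawn(1)[0])

    all_trials = []
    for s, sseed in enumerate(subject_seeds):
        task_seeds = sseed.spawn(2 * len(config.tasks))
        for k, task in enumerate(config.tasks):
            design = ExperimentDesign(
                **{**asdict(config.design), "task": task}
            )
            trials = generate_srt_dataset(design, config.model, task_seeds[2 * k])
            if config.simulate_gaze:
                traces, _ = generate_gaze_dataset(trials, task_seeds[2 * k + 1], config.gaze)
                trials = detect_srts(trials, traces, config.detection)
            else:
                trials = _include_from_ground_truth(trials)
            trials["subject"] = f"S{s}"
            all_trials.append(trials)
    trials = pd.concat(all_trials, ignore_index=True)
    included = trials[trials["included"]].copy()
    if included.empty:
        raise RuntimeError("analysis stage: no trials survived inclusion")

    summaries = []
    reg_rows = []
    per_subject: dict[tuple, list[RegressionResult]] = {}
    for subject, subj_trials in included.groupby("subject", sort=True):
        for task, flash, cell in _analysis_cells(subj_trials):
            try:
                points, _ = inference.condition_summaries(
                    cell, min_n=config.min_fit_n, by=("ecc_dva", "group")
                )
            except ValueError as exc:
                raise RuntimeError(f"fit stage ({subject}/{task}/flash={flash}): {exc}") from exc
            points.insert(0, "subject", subject)
            points.insert(1, "task", task)
            points.insert(2, "flash", flash)
            summaries.append(points)

            for response in ("mode", "fwhm"):
                specs = [("interaction", cell, "combined")] + [
                    ("simple", cell[cell["group"] == g], g) for g in ("Equal", "Scaled")
                ]
                for model, data, scope in specs:
                    res = inference.analyze(
                        data,
                        model=model,
                        response=response,
                        n_perm=config.n_perm,
                        n_boot=config.n_boot,
                        rng=analysis_rng,
                        min_n=config.min_fit_n,
                        run_bootstrap=config.run_bootstrap,
                    )
                    per_subject.setdefault((task, flash, response, model, scope), []).append(res)
                    for coef, est in res.coefficients.items():
                        lo, hi = res.ci_95.get(coef, (np.nan, np.nan))
                        reg_rows.append(
                            {
                                "subject": subject,
                                "task": task,
                                "flash": flash,
                                "response": response,
                                "model": model,
                                "scope": scope,
                                "coefficient": coef,
                                "estimate": est,
                                "ci_low": lo,
                                "ci_high": hi,
                                "p_perm": res.p_perm.get(coef, np.nan),
                            }
                        )

    fixed_rows = []
    if config.n_subjects >= 2:
        for (task, flash, response, model, scope), results in per_subject.items():
            coef = "beta2" if model == "interaction" else "beta1"
            fe: FixedEffectResult = fixed_effect(results, coef)
            fixed_rows.append(
                {
                    "task": task,
                    "flash": flash,
                    "response": response,
                    "model": model,
                    "scope": scope,
                    "coefficient": coef,
                    "mean": fe.mean,
                    "ci_low": fe.ci_95[0] if fe.ci_95 else np.nan,
                    "ci_high": fe.ci_95[1] if fe.ci_95 else np.nan,
                    "p_perm": fe.p_perm if fe.p_perm is not None else np.nan,
                    "n_subjects": fe.n_subjects,
                }
            )

    return RunReport(
        condition_summaries=pd.concat(summaries, ignore_index=True),
        regressions=pd.DataFrame(reg_rows),
        fixed_effects=pd.DataFrame(fixed_rows) if fixed_rows else None,
        trials=trials,
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_trials": int(len(trials)),
            "n_included": int(len(included)),
        },
    )


def write_report(report: RunReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.condition_summaries.to_csv(outdir / "condition_summaries.csv", index=False)
    report.regressions.to_csv(outdir / "regressions.csv", index=False)
    if report.fixed_effects is not None:
        report.fixed_effects.to_csv(outdir / "fixed_effects.csv", index=False)
    report.trials.to_csv(outdir / "trials.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
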