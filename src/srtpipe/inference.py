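"""Condition-level regression of SRT mode/FWHM on eccentricity and scaling.

Each experimental condition (task x flash x eccentricity x scaling group)
contributes one data point: the mode or FWHM of its fitted ex-Gaussian.
Two models are fitted by ordinary least squares on the centred predictor
(eccentricity - 2):

    simple:       y ~ b0 + b1 * (ecc - 2)
    interaction:  y ~ b0 + b1 * (ecc - 2) + b2 * (ecc - 2) * is_scaled

(the interaction model carries no main scaling effect, matching the design
in which both groups share the identical 2-dva reference target).

Significance is assessed by label permutation (two-tailed, add-one
estimator) and uncertainty by a trial-level bootstrap: trials are resampled
with replacement within each condition, the ex-Gaussian refitted, the
summary statistic recomputed, and the regression refitted, yielding a
percentile interval per coefficient.  Across subjects, inference is a fixed
effect: the plain mean of per-subject coefficients, with its CI and p built
from the same per-subject resampling streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exgauss import ExGaussParams, FitResult, fit_mle, fwhm, mode, summarize

__all__ = [
    "RegressionResult",
    "FixedEffectResult",
    "condition_summaries",
    "fit_linear",
    "permutation_test",
    "bootstrap_ci",
    "percent_per_dva",
    "fixed_effect",
    "analyze",
]

_COEF_NAMES = {"simple": ("beta0", "beta1"), "interaction": ("beta0", "beta1", "beta2")}


@dataclass
class RegressionResult:
    """OLS coefficients with permutation p-values and bootstrap 95% CIs."""

    model: str
    response: str
    coefficients: dict[str, float]
    ci_95: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_perm: dict[str, float] = field(default_factory=dict)
    n_points: int = 0
    boot_samples: dict[str, np.ndarray] = field(default_factory=dict)
    perm_samples: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class FixedEffectResult:
    coefficient: str
    mean: float
    ci_95: tuple[float, float] | None
    p_perm: float | None
    n_subjects: int


def condition_summaries(
    trials: pd.DataFrame,
    min_n: int | None = None,
    by: tuple[str, ...] = ("task", "flash", "ecc_dva", "group"),
) -> tuple[pd.DataFrame, dict]:
    """Fit an ex-Gaussian per condition and tabulate mode/FWHM summaries.

    ``trials`` must carry ``srt_ms`` plus the grouping columns.  Returns the
    summary table (one row per condition) and the per-condition FitResults
    keyed by the grouping tuple.
    """
    keys = [k for k in by if k in trials.columns]
    fits: dict = {}
    rows = []
    kwargs = {} if min_n is None else {"min_n": min_n}
    for key, grp in trials.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        fit = fit_mle(grp["srt_ms"].to_numpy(), **kwargs)
        s = summarize(fit.params)
        fits[key] = fit
        row = dict(zip(keys, key))
        row.update(
            {
                "eccentricity": float(row.get("ecc_dva", np.nan)),
                "is_scaled": int(row.get("group") == "Scaled") if "group" in row else 0,
                "mode": s.mode,
                "fwhm": s.fwhm,
                "n_trials": fit.n_trials,
                "converged": fit.converged,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows), fits


def _design(points: pd.DataFrame, model: str) -> np.ndarray:
    x = points["eccentricity"].to_numpy(dtype=float) - 2.0
    if model == "simple":
        return np.column_stack([np.ones_like(x), x])
    if model == "interaction":
        s = points["is_scaled"].to_numpy(dtype=float)
        return np.column_stack([np.ones_like(x), x, x * s])
    raise ValueError(f"unknown model {model!r}")


def fit_linear(points: pd.DataFrame, model: str = "simple", response: str = "mode") -> dict[str, float]:
    """OLS coefficients on the centred predictor; raises on rank deficiency."""
    if len(points) < 3:
        raise ValueError("need at least 3 condition points")
    if model == "interaction" and points["is_scaled"].nunique() < 2:
        raise ValueError("interaction model needs both scaling groups")
    X = _design(points, model)
    y = points[response].to_numpy(dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    return dict(zip(_COEF_NAMES[model], beta.tolist()))


def permutation_test(
    points: pd.DataFrame,
    coefficient: str,
    model: str = "simple",
    response: str = "mode",
    n_perm: int = 1000,
    rng: np.random.Generator | int = 0,
    return_samples: bool = False,
):
    """Two-tailed permutation p for a regression coefficient.

    The permuted label is the regressor the coefficient belongs to: for
    ``beta1`` the eccentricity labels are shuffled across points; for
    ``beta2`` the is_scaled labels are shuffled within each eccentricity,
    preserving the eccentricity margin.  p = (1 + #{|b*| >= |b|}) / (N + 1).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    obs = fit_linear(points, model, response)[coefficient]
    pts = points[["eccentricity", "is_scaled", response]].copy()
    perm_stats = np.empty(n_perm)
    for b in range(n_perm):
        # a shuffled label assignment can occasionally produce a singular
        # design (e.g. the interaction column vanishing on tiny designs);
        # such permutations carry no information about the coefficient and
        # are redrawn
        for _ in range(100):
            p = pts.copy()
            if coefficient == "beta2":
                for _, idx in p.groupby("eccentricity").groups.items():
                    p.loc[idx, "is_scaled"] = rng.permutation(
                        p.loc[idx, "is_scaled"].to_numpy()
                    )
            else:
                p["eccentricity"] = rng.permutation(p["eccentricity"].to_numpy())
            try:
                perm_stats[b] = fit_linear(p, model, response)[coefficient]
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise np.linalg.LinAlgError("could not draw a non-degenerate permutation")
    pval = float((1 + np.sum(np.abs(perm_stats) >= abs(obs))) / (n_perm + 1))
    if return_samples:
        return pval, perm_stats
    return pval


def bootstrap_ci(
    trials: pd.DataFrame,
    model: str = "simple",
    response: str = "mode",
    n_boot: int = 1000,
    level: float = 95.0,
    rng: np.random.Generator | int = 0,
    min_n: int | None = None,
    max_failure_rate: float = 0.05,
) -> tuple[dict[str, tuple[float, float]], dict[str, np.ndarray]]:
    """Trial-level bootstrap percentile CIs for the regression coefficients.

    Each replicate resamples trials with replacement within each condition
    (ecc_dva x group), refits the ex-Gaussian (warm-started at the full-data
    fit), recomputes the summary statistic, and refits the regression.
    Aborts if more than ``max_failure_rate`` of replicates fail.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    kwargs = {} if min_n is None else {"min_n": min_n}
    conds = []
    for key, grp in trials.groupby(["ecc_dva", "group"], sort=True):
        srts = grp["srt_ms"].to_numpy()
        full = fit_mle(srts, **kwargs)
        conds.append((key, srts, full.params))

    names = _COEF_NAMES[model]
    samples = {c: np.full(n_boot, np.nan) for c in names}
    failures = 0
    for b in range(n_boot):
        rows = []
        try:
            for (ecc, group), srts, warm in conds:
                res = srts[rng.integers(0, len(srts), len(srts))]
                fit = fit_mle(res, start=warm, **kwargs)
                m = mode(fit.params)
                val = m if response == "mode" else fwhm(fit.params, _mode=m)
                rows.append(
                    {"eccentricity": ecc, "is_scaled": int(group == "Scaled"), response: val}
                )
            beta = fit_linear(pd.DataFrame(rows), model, response)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        for c in names:
            samples[c][b] = beta[c]
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(f"bootstrap failure rate {failures}/{n_boot} exceeds {max_failure_rate:.0%}")

    alpha = (100.0 - level) / 2.0
    ci = {}
    for c in names:
        s = samples[c][np.isfinite(samples[c])]
        ci[c] = (float(np.percentile(s, alpha)), float(np.percentile(s, 100.0 - alpha)))
    return ci, samples


def percent_per_dva(coefficient: float, intercept: float) -> float:
    """Raw slope (ms/dva) as percent increase per dva of the 2-dva value."""
    if intercept <= 0:
        raise ValueError("intercept must be positive")
    return 100.0 * coefficient / intercept


def fixed_effect(per_subject: list[RegressionResult], coefficient: str) -> FixedEffectResult:
    """Fixed-effect aggregate: mean per-subject coefficient.

    The CI averages the per-subject bootstrap streams replicate-by-replicate
    and takes percentiles; the p-value compares |mean| against the mean of
    the per-subject permutation streams.  Both require the per-subject
    results to carry their resampling samples.
    """
    if len(per_subject) < 2:
        raise ValueError("fixed effect needs at least 2 subjects")
    for r in per_subject:
        if coefficient not in r.coefficients:
            raise ValueError(f"coefficient {coefficient!r} missing from a subject result")
    coefs = np.array([r.coefficients[coefficient] for r in per_subject])
    mean = float(np.mean(coefs))

    ci = None
    boots = [r.boot_samples.get(coefficient) for r in per_subject]
    if all(b is not None for b in boots):
        nb = min(len(b) for b in boots)
        stacked = np.vstack([b[:nb] for b in boots])
        means = np.nanmean(stacked, axis=0)
        means = means[np.isfinite(means)]
        ci = (float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5)))

    p = None
    perms = [r.perm_samples.get(coefficient) for r in per_subject]
    if all(pp is not None for pp in perms):
        np_ = min(len(pp) for pp in perms)
        perm_means = np.vstack([pp[:np_] for pp in perms]).mean(axis=0)
        p = float((1 + np.sum(np.abs(perm_means) >= abs(mean))) / (len(perm_means) + 1))

    return FixedEffectResult(
        coefficient=coefficient, mean=mean, ci_95=ci, p_perm=p, n_subjects=len(per_subject)
    )


def analyze(
    trials: pd.DataFrame,
    model: str = "interaction",
    response: str = "mode",
    n_perm: int = 1000,
    n_boot: int = 1000,
    rng: np.random.Generator | int = 0,
    min_n: int | None = None,
    run_bootstrap: bool = True,
) -> RegressionResult:
    """Full condition-level analysis of one trial table (one task x flash cell)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    points, _ = condition_summaries(trials, min_n=min_n, by=("ecc_dva", "group"))
    coefs = fit_linear(points, model, response)
    result = RegressionResult(
        model=model, response=response, coefficients=coefs, n_points=len(points)
    )
    for c in _COEF_NAMES[model][1:]:
        pval, ps = permutation_test(
            points, c, model, response, n_perm=n_perm, rng=rng, return_samples=True
        )
        result.p_perm[c] = pval
        result.perm_samples[c] = ps
    if run_bootstrap:
        ci, samples = bootstrap_ci(
            trials, model, response, n_boot=n_boot, rng=rng, min_n=min_n
        )
        result.ci_95 = ci
        result.boot_samples = samples
    return result
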