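"""Regression, permutation, bootstrap, percent conversion, fixed effects."""

import numpy as np
import pandas as pd
import pytest

from srtpipe import exgauss
from srtpipe.inference import (
    RegressionResult,
    bootstrap_ci,
    condition_summaries,
    fit_linear,
    fixed_effect,
    percent_per_dva,
    permutation_test,
)
from srtpipe.synthetic_data import ExperimentDesign, GenerativeSRTModel, generate_srt_dataset

ECCS = [2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0]


def points_on_line(intercept, slope_equal, slope_scaled=None):
    rows = []
    for ecc in ECCS:
        rows.append({"eccentricity": ecc, "is_scaled": 0,
                     "mode": intercept + slope_equal * (ecc - 2)})
        if slope_scaled is not None:
            rows.append({"eccentricity": ecc, "is_scaled": 1,
                         "mode": intercept + slope_scaled * (ecc - 2)})
    return pd.DataFrame(rows)


class TestFitLinear:
    def test_noiseless_simple_line(self):
        beta = fit_linear(points_on_line(150.0, 5.0), "simple")
        assert beta["beta0"] == pytest.approx(150.0, abs=1e-10)
        assert beta["beta1"] == pytest.approx(5.0, abs=1e-10)

    def test_interaction_recovers_slope_difference(self):
        beta = fit_linear(points_on_line(150.0, 5.0, 1.0), "interaction")
        assert beta["beta1"] == pytest.approx(5.0, abs=1e-10)
        assert beta["beta2"] == pytest.approx(-4.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        pts = points_on_line(160.0, 4.0, 0.5)
        pts["mode"] += rng.normal(0, 3.0, len(pts))
        x = pts["eccentricity"].to_numpy() - 2.0
        X = np.column_stack([np.ones(len(pts)), x, x * pts["is_scaled"].to_numpy()])
        y = pts["mode"].to_numpy()
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        beta = fit_linear(pts, "interaction")
        assert beta["beta0"] == pytest.approx(oracle[0], abs=1e-10)
        assert beta["beta1"] == pytest.approx(oracle[1], abs=1e-10)
        assert beta["beta2"] == pytest.approx(oracle[2], abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        pts = points_on_line(160.0, 4.0)
        pts["mode"] += rng.normal(0, 2.0, len(pts))
        x = pts["eccentricity"].to_numpy() - 2.0
        ref = sm.OLS(pts["mode"].to_numpy(), sm.add_constant(x)).fit()
        beta = fit_linear(pts, "simple")
        assert beta["beta0"] == pytest.approx(ref.params[0], abs=1e-8)
        assert beta["beta1"] == pytest.approx(ref.params[1], abs=1e-8)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_linear(points_on_line(150.0, 5.0).head(2), "simple")
        with pytest.raises(ValueError):
            fit_linear(points_on_line(150.0, 5.0), "interaction")  # one group only


class TestPermutation:
    def test_huge_effect_reaches_lower_bound(self):
        pts = points_on_line(150.0, 10.0)
        p = permutation_test(pts, "beta1", n_perm=200, rng=0)
        assert p == pytest.approx(1.0 / 201.0)

    def test_p_within_bounds_and_deterministic(self):
        rng = np.random.default_rng(2)
        pts = points_on_line(150.0, 0.0)
        pts["mode"] += rng.normal(0, 5.0, len(pts))
        p1 = permutation_test(pts, "beta1", n_perm=99, rng=7)
        p2 = permutation_test(pts, "beta1", n_perm=99, rng=7)
        assert p1 == p2
        assert 1.0 / 100.0 <= p1 <= 1.0

    def test_beta2_permutes_within_eccentricity(self):
        """With is_scaled shuffled within eccentricity, a strong interaction
        stands out while the common slope is preserved under the null.  With
        7 eccentricities there are only 2^7 distinct label patterns and the
        observed |beta2| recurs under the all-swapped pattern, so the p-value
        sits near 2/128 rather than at the 1/(N+1) floor."""
        pts = points_on_line(150.0, 5.0, 0.0)
        p = permutation_test(pts, "beta2", model="interaction", n_perm=200, rng=3)
        assert p < 0.05


@pytest.fixture(scope="module")
def trials():
    design = ExperimentDesign(task="Step", trials_per_condition=80, groups=("Equal",))
    model = GenerativeSRTModel(base_mode=160.0, slope_equal=4.0, fwhm_slope=0.0)
    df = generate_srt_dataset(design, model, seed=5)
    df["srt_ms"] = df["true_srt_ms"]
    return df


class TestBootstrap:
    def test_interval_contains_generative_slope(self, trials):
        ci, _ = bootstrap_ci(trials, "simple", "mode", n_boot=100, rng=1)
        lo, hi = ci["beta1"]
        assert lo < 4.0 < hi

    def test_same_seed_identical_intervals(self, trials):
        a, _ = bootstrap_ci(trials, "simple", "mode", n_boot=50, rng=9)
        b, _ = bootstrap_ci(trials, "simple", "mode", n_boot=50, rng=9)
        assert a == b

    def test_point_estimate_inside_own_interval(self, trials):
        points, _ = condition_summaries(trials, by=("ecc_dva", "group"))
        est = fit_linear(points, "simple")["beta1"]
        ci, samples = bootstrap_ci(trials, "simple", "mode", n_boot=100, rng=2)
        lo, hi = ci["beta1"]
        # percentile interval of the coefficient's own bootstrap sample
        assert lo <= np.nanmedian(samples["beta1"]) <= hi
        assert lo < est < hi


def test_percent_per_dva():
    assert percent_per_dva(4.0, 200.0) == pytest.approx(2.0)
    assert percent_per_dva(0.0, 200.0) == 0.0
    with pytest.raises(ValueError):
        percent_per_dva(4.0, 0.0)


def test_percent_per_dva_roundtrip_through_generator():
    """FWHM generated with 3%/dva of its 2-dva value is recovered."""
    base_fwhm = 60.0
    model = GenerativeSRTModel(
        base_mode=160.0, slope_equal=0.0, base_fwhm=base_fwhm,
        fwhm_slope=0.03 * base_fwhm,
    )
    design = ExperimentDesign(task="Step", trials_per_condition=400, groups=("Equal",))
    trials = generate_srt_dataset(design, model, seed=11)
    trials["srt_ms"] = trials["true_srt_ms"]
    points, _ = condition_summaries(trials, by=("ecc_dva", "group"))
    beta = fit_linear(points, "simple", response="fwhm")
    pct = percent_per_dva(beta["beta1"], beta["beta0"])
    assert pct == pytest.approx(3.0, abs=1.0)


class TestFixedEffect:
    @staticmethod
    def result(coef, boot=None, perm=None):
        return RegressionResult(
            model="simple",
            response="mode",
            coefficients={"beta1": coef},
            boot_samples={"beta1": boot} if boot is not None else {},
            perm_samples={"beta1": perm} if perm is not None else {},
        )

    def test_mean_of_subject_slopes(self):
        fe = fixed_effect([self.result(c) for c in (4.0, 5.0, 6.0)], "beta1")
        assert fe.mean == pytest.approx(5.0)
        assert fe.n_subjects == 3

    def test_identical_subjects_zero_width(self):
        boot = np.full(100, 3.0)
        fe = fixed_effect([self.result(3.0, boot=boot)] * 3, "beta1")
        assert fe.mean == 3.0
        assert fe.ci_95 == (3.0, 3.0)

    def test_recovers_common_effect_with_resampling(self):
        rng = np.random.default_rng(4)
        results = []
        for _ in range(4):
            c = -3.0 + rng.normal(0, 0.3)
            results.append(
                self.result(c, boot=c + rng.normal(0, 0.5, 200), perm=rng.normal(0, 0.5, 200))
            )
        fe = fixed_effect(results, "beta1")
        assert fe.ci_95[0] < -3.0 < fe.ci_95[1]
        assert fe.p_perm < 0.05

    def test_errors(self):
        with pytest.raises(ValueError):
            fixed_effect([self.result(4.0)], "beta1")
        with pytest.raises(ValueError):
            fixed_effect([self.result(4.0), self.result(5.0)], "beta2")


def test_condition_summaries_shape():
    design = ExperimentDesign(task="Step", trials_per_condition=60, eccentricities=(2, 6))
    trials = generate_srt_dataset(design, GenerativeSRTModel(), seed=6)
    trials["srt_ms"] = trials["true_srt_ms"]
    points, fits = condition_summaries(trials, by=("ecc_dva", "group"))
    assert len(points) == 4  # 2 eccs x 2 groups
    assert set(points["is_scaled"]) == {0, 1}
    assert (points["n_trials"] == 60).all()
    assert len(fits) == 4
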