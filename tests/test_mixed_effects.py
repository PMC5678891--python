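import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.stats import norm

from vo2kinetics import (
    KineticParams,
    ModelFamily,
    align_to_lam_max,
    bin_cohort,
    generate_cohort,
)
from vo2kinetics.mixed_effects import NlmeSpec, fit_nlme, stage_estimates
from vo2kinetics.models import evaluate
from vo2kinetics.synthetic import RANDOM_PARAMS, CohortSpec

from conftest import small_cohort_spec

TRUTH_T_HALF = {2: 128.0, 3: 133.0, 4: 168.0}


def make_cohort(seed=7, n=5, **overrides):
    records, truth = generate_cohort(small_cohort_spec(seed=seed, n=n, **overrides))
    return align_to_lam_max(bin_cohort(records, 20.0)), truth


class TestFitNlme:
    def test_stage_t_half_within_three_se(self, small_cohort):
        series, _ = small_cohort
        fit = fit_nlme(series, NlmeSpec("log_logistic"))
        assert fit.converged
        est = stage_estimates(fit, "t_half")
        for s, th, se in zip(est.stages, est.estimates, est.ses):
            assert abs(th - TRUTH_T_HALF[s]) < 3.0 * se

    def test_no_random_effects_equals_pooled_nls_oracle(self, small_cohort):
        series, _ = small_cohort
        fit = fit_nlme(series, NlmeSpec("log_logistic", random_params=()))
        assert fit.converged
        lam_max = series[0].lam_max
        template = KineticParams(300, 1000, 400, 30, -2, 120, lam_max, lam_max)

        def f(t, *x):
            return evaluate(t, template.with_free_values(x), "log_logistic",
                            validate=False)

        for si, stage in enumerate(fit.stages):
            t = np.concatenate([s.times for s in series if s.stage == stage])
            y = np.concatenate([s.vo2 for s in series if s.stage == stage])
            popt, _ = curve_fit(f, t, y, p0=fit.beta[:, si] * 1.05, maxfev=20000)
            rel = np.abs(popt - fit.beta[:, si]) / np.maximum(np.abs(popt), 1e-8)
            assert rel.max() < 1e-4

    def test_zero_variance_zero_noise_degenerate(self):
        series, _ = make_cohort(
            seed=5, n=3, noise_sd=0.0, random_sd={k: 0.0 for k in RANDOM_PARAMS}
        )
        fit = fit_nlme(series, NlmeSpec("log_logistic"))
        assert fit.converged
        # residual variance reduces to the tiny within-bin averaging error,
        # so the random-effect covariance collapses
        assert np.abs(fit.G_hat).max() < 1.0
        for si, stage in enumerate(fit.stages):
            assert abs(fit.beta[5, si] - TRUTH_T_HALF[stage]) < 0.5

    def test_full_g_nests_diagonal(self, small_cohort):
        series, _ = small_cohort
        diag = fit_nlme(series, NlmeSpec("log_logistic", g_structure="diagonal"))
        full = fit_nlme(series, NlmeSpec("log_logistic", g_structure="full"))
        assert full.loglik >= diag.loglik - 0.1
        assert full.G_hat.shape == (4, 4)
        # G stays symmetric positive semidefinite
        np.testing.assert_allclose(full.G_hat, full.G_hat.T)
        assert np.linalg.eigvalsh(full.G_hat).min() > -1e-8

    def test_loglik_increases_across_outer_iterations(self, small_cohort):
        series, _ = small_cohort
        fit = fit_nlme(series, NlmeSpec("log_logistic"))
        # monotone up to re-linearization error: each outer step changes the
        # expansion point, so small decrements of order 1e-4 relative occur
        path = np.asarray(fit.loglik_path)
        tol = 1e-4 * (np.abs(path).max() + 1.0)
        assert np.all(np.diff(path) >= -tol)

    def test_aic_prefers_generating_family(self):
        wins, reps = 0, 6
        for rep in range(reps):
            series, _ = make_cohort(seed=3000 + rep, n=5)
            aics = {
                fam: fit_nlme(series, NlmeSpec(fam)).aic for fam in ModelFamily
            }
            wins += min(aics, key=aics.get) is ModelFamily.LOG_LOGISTIC
        assert wins >= 5

    def test_unaligned_cohort_rejected(self):
        records, _ = generate_cohort(small_cohort_spec(seed=1, n=2))
        series = bin_cohort(records, 20.0)  # not aligned
        with pytest.raises(ValueError, match="align"):
            fit_nlme(series, NlmeSpec("log_logistic"))


class TestStageEstimates:
    def test_confidence_interval_coverage(self):
        covered, total = 0, 0
        for rep in range(20):
            series, _ = make_cohort(seed=4000 + rep, n=5)
            fit = fit_nlme(series, NlmeSpec("log_logistic"))
            if not fit.converged:
                continue
            est = stage_estimates(fit, "t_half")
            z = norm.ppf(0.975)
            for s, th, se in zip(est.stages, est.estimates, est.ses):
                covered += abs(th - TRUTH_T_HALF[s]) < z * se
                total += 1
        assert total >= 45
        assert covered / total >= 0.80

    def test_single_stage_cohort_returns_one_level(self):
        records, _ = generate_cohort(CohortSpec(n_per_stage={3: 5}, seed=6))
        series = align_to_lam_max(bin_cohort(records, 20.0))
        fit = fit_nlme(series, NlmeSpec("log_logistic"))
        est = stage_estimates(fit, "t_half")
        assert list(est.stages) == [3]
        assert est.estimates.shape == (1,)

    def test_constant_truth_gives_equal_stage_estimates(self):
        means = small_cohort_spec().stage_means
        same = {s: means[3] for s in (2, 3, 4)}
        records, _ = generate_cohort(
            small_cohort_spec(seed=12, n=5, stage_means=same)
        )
        series = align_to_lam_max(bin_cohort(records, 20.0))
        est = stage_estimates(fit_nlme(series, NlmeSpec("log_logistic")), "t_half")
        for i in range(3):
            for j in range(i + 1, 3):
                se = np.hypot(est.ses[i], est.ses[j])
                assert abs(est.estimates[i] - est.estimates[j]) < 3.0 * se

    def test_unknown_parameter_rejected(self, small_cohort):
        series, _ = small_cohort
        fit = fit_nlme(series, NlmeSpec("log_logistic"))
        with pytest.raises(KeyError):
            stage_estimates(fit, "nonsense")
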