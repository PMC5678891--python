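import numpy as np
import pytest

from vo2kinetics import (
    CohortSpec,
    KineticParams,
    ModelFamily,
    PatientSeries,
    align_to_lam_max,
    bin_cohort,
    evaluate,
    fit_cohort,
    generate_cohort,
)
from vo2kinetics.models import PARAM_NAMES, TAU2_SIGN


def canonical_params(family=ModelFamily.LOG_LOGISTIC, **overrides) -> KineticParams:
    """A reference parameter set with the family's canonical tau2 sign."""
    values = dict(
        vo2_rest=300.0, vo2_ss=1000.0, vo2_rec=400.0,
        tau1=30.0, tau2=2.0 * TAU2_SIGN[ModelFamily.coerce(family)],
        t_half=120.0, lam=60.0, lam_max=60.0,
    )
    values.update(overrides)
    return KineticParams(**values)


def model_series(
    p: KineticParams,
    family=ModelFamily.LOG_LOGISTIC,
    bin_width: float = 20.0,
    recovery: float = 600.0,
    stage: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PatientSeries:
    """A binned series lying exactly on the model curve (plus optional noise).

    Values are the curve at the bin midpoints, so a noise-free series is
    recovered exactly by the fit (no within-bin averaging bias).
    """
    t_end = p.lam_max + 360.0 + recovery
    times = np.arange(bin_width / 2.0, t_end, bin_width)
    vo2 = evaluate(times, p, family)
    if noise_sd > 0:
        vo2 = vo2 + np.random.default_rng(seed).normal(0.0, noise_sd, times.size)
    return PatientSeries(
        patient_id="p1", stage=stage, lam=p.lam, times=times, vo2=vo2,
        bin_width=bin_width, lam_max=p.lam_max,
    )


def finite_difference(t, p: KineticParams, family, rel_step: float = 1e-6):
    """Central finite-difference Jacobian of the kinetic curve."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    x = p.free_values()
    out = np.zeros((t.size, len(PARAM_NAMES)))
    for k in range(len(PARAM_NAMES)):
        h = rel_step * max(1.0, abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        fp = evaluate(t, p.with_free_values(xp), family, validate=False)
        fm = evaluate(t, p.with_free_values(xm), family, validate=False)
        out[:, k] = (fp - fm) / (2.0 * h)
    return out


def small_cohort_spec(seed: int = 7, n: int = 5, **overrides) -> CohortSpec:
    return CohortSpec(n_per_stage={2: n, 3: n, 4: n}, seed=seed, **overrides)


@pytest.fixture(scope="session")
def small_cohort():
    """A 15-patient cohort binned, aligned, with its truth ledger."""
    records, truth = generate_cohort(small_cohort_spec())
    series = align_to_lam_max(bin_cohort(records, 20.0))
    return series, truth


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    series, truth = small_cohort
    return series, truth, fit_cohort(series, [ModelFamily.LOG_LOGISTIC])
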