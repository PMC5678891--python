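"""Nonlinear models for oxygen-uptake (V̇O2) kinetics around a 6-min walk test.

A kinetic trace has three phases: rest (constant ``vo2_rest``), a 360-s
walking phase during which uptake rises mono-exponentially towards
``vo2_ss``, and a post-exercise recovery during which uptake decays
sigmoidally towards ``vo2_rec``.  The recovery sigmoid comes in three
families — a symmetric log-logistic and two asymmetric Weibull shapes with
the inflection early (Weibull 1) or late (Weibull 2) in the recovery:

    V̇O2(t) = vo2_rest
            + (vo2_ss − vo2_rest) · (1 − exp(−(t − λ)/τ1))          [t > λ]
            + (vo2_rec − vo2_ss) · R(t)                              [t > t0]

with t0 = λmax + 360 the common recovery onset of a cohort aligned on the
longest resting phase λmax, and, writing s = τ2·log((t − t0)/T½),

    log-logistic:  R = 1 / (1 + exp(s))
    Weibull 1:     R = exp(−exp(s))
    Weibull 2:     R = 1 − exp(−exp(s))

T½ (``t_half``) is the recovery time-scale; for the log-logistic family it
is exactly the time after t0 at which half the V̇O2 decrease is achieved.
The direction of each sigmoid is set by the sign of τ2: negative for the
log-logistic and Weibull 1 families, positive for Weibull 2.  Both
time-varying components are gated to zero before their onsets so the model
is a total function of t.

All times are in seconds, all uptake values in mL/min.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.special import expit

__all__ = [
    "WALK_DURATION",
    "PARAM_NAMES",
    "ModelFamily",
    "KineticParams",
    "exercise_component",
    "recovery_component",
    "evaluate",
    "gradient",
    "mean_response_time",
]

#: Length of the walking phase of a 6-min walk test, seconds.
WALK_DURATION = 360.0

#: Order of the six free curve parameters everywhere in the package.
PARAM_NAMES = ("vo2_rest", "vo2_ss", "vo2_rec", "tau1", "tau2", "t_half")


class ModelFamily(str, Enum):
    """The three recovery-sigmoid families."""

    LOG_LOGISTIC = "log_logistic"
    WEIBULL_1 = "weibull_1"
    WEIBULL_2 = "weibull_2"

    @classmethod
    def coerce(cls, value: "ModelFamily | str") -> "ModelFamily":
        return value if isinstance(value, cls) else cls(str(value))


#: Canonical sign of tau2 per family (used for initialization only).
TAU2_SIGN = {
    ModelFamily.LOG_LOGISTIC: -1.0,
    ModelFamily.WEIBULL_1: -1.0,
    ModelFamily.WEIBULL_2: +1.0,
}


@dataclass(frozen=True)
class KineticParams:
    """Parameters of one kinetic curve.

    The six curve parameters (``vo2_rest``, ``vo2_ss``, ``vo2_rec``,
    ``tau1``, ``tau2``, ``t_half``) are free in fitting; ``lam`` (individual
    resting-phase length λ) and ``lam_max`` (cohort maximum, fixing the
    recovery onset at ``lam_max + 360``) are experimenter-controlled and
    never estimated.  For series aligned on the cohort's longest rest,
    ``lam == lam_max``.
    """

    vo2_rest: float  # uptake at rest, mL/min
    vo2_ss: float    # steady-state uptake during walking, mL/min
    vo2_rec: float   # recovered uptake plateau, mL/min
    tau1: float      # exercise mono-exponential time constant, s
    tau2: float      # recovery steepness (dimensionless, signed)
    t_half: float    # recovery time-scale T1/2, s
    lam: float       # resting-phase length λ, s (fixed)
    lam_max: float   # cohort maximum resting length λmax, s (fixed)

    @property
    def recovery_onset(self) -> float:
        """t0 = λmax + 360, the common recovery onset (s)."""
        return self.lam_max + WALK_DURATION

    def validate(self) -> None:
        problems = []
        if not self.vo2_rest > 0:
            problems.append(f"vo2_rest must be > 0, got {self.vo2_rest}")
        if not self.vo2_ss > self.vo2_rest:
            problems.append(
                f"vo2_ss ({self.vo2_ss}) must exceed vo2_rest ({self.vo2_rest})"
            )
        if not self.vo2_rec < self.vo2_ss:
            problems.append(
                f"vo2_rec ({self.vo2_rec}) must be below vo2_ss ({self.vo2_ss})"
            )
        if not self.tau1 > 0:
            problems.append(f"tau1 must be > 0, got {self.tau1}")
        if not self.t_half > 0:
            problems.append(f"t_half must be > 0, got {self.t_half}")
        if not (0 <= self.lam <= self.lam_max):
            problems.append(
                f"need 0 <= lam <= lam_max, got lam={self.lam}, lam_max={self.lam_max}"
            )
        if problems:
            raise ValueError("invalid kinetic parameters: " + "; ".join(problems))

    def free_values(self) -> np.ndarray:
        """The six free parameters in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    def with_free_values(self, values) -> "KineticParams":
        values = np.asarray(values, dtype=float)
        return replace(self, **dict(zip(PARAM_NAMES, values)))


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    return t


def exercise_component(t, p: KineticParams, validate: bool = True) -> np.ndarray:
    """Mono-exponential exercise rise, zero before exercise onset λ."""
    if validate:
        p.validate()
    t = _check_times(t)
    dt = np.maximum(t - p.lam, 0.0)
    return -(p.vo2_ss - p.vo2_rest) * np.expm1(-dt / p.tau1)


def _recovery_fraction(t, p: KineticParams, family: ModelFamily) -> np.ndarray:
    """R(t) in [0, 1): fraction of the recovery decrease achieved at t."""
    t0 = p.recovery_onset
    dt = np.asarray(t, dtype=float) - t0
    active = dt > 0.0
    frac = np.zeros_like(dt)
    if np.any(active):
        s = p.tau2 * np.log(dt[active] / p.t_half)
        s = np.clip(s, -700.0, 700.0)
        if family is ModelFamily.LOG_LOGISTIC:
            frac[active] = expit(-s)
        elif family is ModelFamily.WEIBULL_1:
            frac[active] = np.exp(-np.exp(s))
        else:
            frac[active] = -np.expm1(-np.exp(s))
    return frac


def recovery_component(t, p: KineticParams, family, validate: bool = True) -> np.ndarray:
    """Recovery sigmoid scaled by (vo2_rec − vo2_ss); zero up to t0."""
    if validate:
        p.validate()
    family = ModelFamily.coerce(family)
    t = _check_times(t)
    return (p.vo2_rec - p.vo2_ss) * _recovery_fraction(t, p, family)


def evaluate(t, p: KineticParams, family, validate: bool = True) -> np.ndarray:
    """Full three-phase V̇O2 curve at times ``t`` (vectorized)."""
    return (
        p.vo2_rest
        + exercise_component(t, p, validate=validate)
        + recovery_component(t, p, family, validate=False if not validate else True)
    )


def gradient(t, p: KineticParams, family, validate: bool = True) -> np.ndarray:
    """Analytic Jacobian ∂V̇O2/∂(6 free params), shape ``(len(t), 6)``.

    Columns follow :data:`PARAM_NAMES`.  Used for least-squares fitting and
    for standard errors; agrees with central finite differences.
    """
    if validate:
        p.validate()
    family = ModelFamily.coerce(family)
    t = np.atleast_1d(_check_times(t))

    grad = np.zeros((t.size, 6))

    # exercise phase
    dt_ex = np.maximum(t - p.lam, 0.0)
    e = -np.expm1(-dt_ex / p.tau1)  # E(t) in [0, 1)
    span_ex = p.vo2_ss - p.vo2_rest
    grad[:, 0] = 1.0 - e                      # d/d vo2_rest
    grad[:, 1] = e                            # d/d vo2_ss (exercise part)
    grad[:, 3] = -span_ex * (dt_ex / p.tau1**2) * np.exp(-dt_ex / p.tau1)

    # recovery phase
    t0 = p.recovery_onset
    dt = t - t0
    active = dt > 0.0
    if np.any(active):
        span_rec = p.vo2_rec - p.vo2_ss
        u = np.log(dt[active] / p.t_half)
        s = np.clip(p.tau2 * u, -700.0, 700.0)
        if family is ModelFamily.LOG_LOGISTIC:
            frac = expit(-s)
            dfrac_ds = -expit(s) * expit(-s)
        elif family is ModelFamily.WEIBULL_1:
            frac = np.exp(-np.exp(s))
            dfrac_ds = -np.exp(s - np.exp(s))
        else:
            frac = -np.expm1(-np.exp(s))
            dfrac_ds = np.exp(s - np.exp(s))
        grad[active, 1] -= frac               # d/d vo2_ss (recovery part)
        grad[active, 2] = frac                # d/d vo2_rec
        grad[active, 4] = span_rec * dfrac_ds * u
        grad[active, 5] = span_rec * dfrac_ds * (-p.tau2 / p.t_half)
    return grad


def mean_response_time(p: KineticParams) -> float:
    """Mean response time (MRT) of the exercise rise.

    The time after exercise onset at which the mono-exponential reaches
    1 − e⁻¹ ≈ 63% of its span; equals ``tau1``.
    """
    if not p.tau1 > 0:
        raise ValueError("tau1 must be positive")
    return p.tau1
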