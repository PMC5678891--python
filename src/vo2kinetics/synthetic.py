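"""Synthetic breath-by-breath cohorts with known ground truth.

The generator reproduces the statistical structure the analysis assumes: a
cohort of COPD patients across GOLD stages 2/3/4 (21/30/10 by default),
each with an individually drawn resting phase λᵢ, a 360-s walk and a
recovery phase; patient-level heterogeneity as independent Gaussian random
effects on the four recovery parameters (vo2_ss, t_half, tau2, vo2_rec);
and i.i.d. Gaussian residual noise on every breath.  Breath times arrive at
jittered 2–4 s intervals, realistic input for 20-s binning.

Every cohort comes with a truth ledger (all patient-level parameters) so
parameter-recovery tests can compare estimates against the values that
generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import KineticParams, ModelFamily, WALK_DURATION, evaluate

__all__ = ["CohortSpec", "default_truth", "generate_cohort"]

RANDOM_PARAMS = ("vo2_ss", "t_half", "tau2", "vo2_rec")


def _default_stage_means() -> dict[int, KineticParams]:
    # Plausible magnitudes for a COPD cohort: recovery half-times that grow
    # with disease severity (~128/133/168 s) and exercise spans that shrink
    # with it; documented as realistic defaults, not as clinical ground truth.
    return {
        2: KineticParams(310.0, 1310.0, 410.0, 30.0, -2.0, 128.0, 0.0, 0.0),
        3: KineticParams(300.0, 1150.0, 400.0, 35.0, -2.0, 133.0, 0.0, 0.0),
        4: KineticParams(290.0, 990.0, 400.0, 40.0, -2.0, 168.0, 0.0, 0.0),
    }


def _default_random_sd() -> dict[str, float]:
    return {"vo2_ss": 80.0, "t_half": 25.0, "tau2": 0.3, "vo2_rec": 40.0}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_per_stage: dict[int, int] = field(default_factory=lambda: {2: 21, 3: 30, 4: 10})
    family_truth: ModelFamily = ModelFamily.LOG_LOGISTIC
    stage_means: dict[int, KineticParams] = field(default_factory=_default_stage_means)
    random_sd: dict[str, float] = field(default_factory=_default_random_sd)
    noise_sd: float = 100.0         # mL/min per breath; ≈5% of the exercise span
                                    # after 20-s binning (breath noise averages down
                                    # by ~sqrt(breaths per bin))
    lam_range: tuple[float, float] = (30.0, 90.0)  # per-patient resting length, s
    breath_interval: tuple[float, float] = (2.0, 4.0)  # jittered gap between breaths, s
    recovery_duration: float = 600.0  # recorded recovery, s (~3.5× the slowest
                                      # stage's T1/2 so the plateau is reached)
    seed: int = 0

    def validate(self) -> None:
        if any(n < 1 for n in self.n_per_stage.values()):
            raise ValueError("need at least one patient per stage")
        if any(sd < 0 for sd in self.random_sd.values()) or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        lo, hi = self.lam_range
        if not (0 <= lo <= hi):
            raise ValueError("lam_range must satisfy 0 <= lo <= hi")
        for stage, p in self.stage_means.items():
            p.validate()


def default_truth() -> CohortSpec:
    """The default study conditions (61 patients, log-logistic truth)."""
    return CohortSpec()


def _draw_patient_params(
    mean: KineticParams, random_sd: dict[str, float], rng: np.random.Generator,
    max_attempts: int = 100,
) -> KineticParams:
    names = [k for k in RANDOM_PARAMS if random_sd.get(k, 0.0) > 0]
    for _ in range(max_attempts):
        draw = {k: getattr(mean, k) + rng.normal(0.0, random_sd[k]) for k in names}
        candidate = replace(mean, **draw)
        try:
            candidate.validate()
        except ValueError:
            continue
        return candidate
    raise RuntimeError(
        "could not draw valid patient parameters in "
        f"{max_attempts} attempts; random_sd too large for the stage means"
    )


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None):
    """Simulate one cohort.

    Returns ``(records, truth)``: a long-format breath table with columns
    ``patient_id, stage, lam, time_s, vo2_ml_min`` and a truth ledger with
    one row per patient carrying λᵢ and the six curve parameters actually
    used.  Fully reproducible given the seed (``seed`` overrides
    ``spec.seed`` when given).
    """
    spec = spec or default_truth()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    record_parts = []
    truth_rows = []
    for stage in sorted(spec.n_per_stage):
        n = spec.n_per_stage[stage]
        mean = spec.stage_means[stage]
        for j in range(n):
            pid = f"s{stage}p{j + 1:02d}"
            lam = rng.uniform(*spec.lam_range)
            p = _draw_patient_params(mean, spec.random_sd, rng)
            # in raw (unaligned) patient time the recovery starts at λᵢ+360
            p = replace(p, lam=lam, lam_max=lam)
            t_end = lam + WALK_DURATION + spec.recovery_duration
            gaps = rng.uniform(*spec.breath_interval, size=int(t_end / spec.breath_interval[0]) + 2)
            times = np.cumsum(gaps)
            times = times[times <= t_end]
            vo2 = evaluate(times, p, spec.family_truth)
            if spec.noise_sd > 0:
                noisy = vo2 + rng.normal(0.0, spec.noise_sd, size=times.size)
                # uptake is physically positive; redraw the rare breath whose
                # noise pushes it below zero (negligible truncation at the
                # default rest level of ~3 noise SDs above zero)
                bad = noisy <= 0
                while np.any(bad):
                    noisy[bad] = vo2[bad] + rng.normal(0.0, spec.noise_sd, size=int(bad.sum()))
                    bad = noisy <= 0
                vo2 = noisy
            record_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "stage": stage,
                        "lam": lam,
                        "time_s": times,
                        "vo2_ml_min": vo2,
                    }
                )
            )
            truth_rows.append(
                {
                    "patient_id": pid,
                    "stage": stage,
                    "lam": lam,
                    "vo2_rest": p.vo2_rest,
                    "vo2_ss": p.vo2_ss,
                    "vo2_rec": p.vo2_rec,
                    "tau1": p.tau1,
                    "tau2": p.tau2,
                    "t_half": p.t_half,
                }
            )
    records = pd.concat(record_parts, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return records, truth
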