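"""AIC-based multimodel inference: Akaike weights, model averaging, subgroup selection.

Given information criteria IC_p for P candidate models, the Akaike weight
of model p is w_p = exp(−Δ_p/2) / Σ_r exp(−Δ_r/2) with Δ_p = IC_p − min IC.
The model-averaged estimate of a focal quantity is θ̂_MA = Σ w_p θ̂_p, and
its conservative unconditional standard error follows Buckland's form

    SE_MA = Σ_p w_p · sqrt(var(θ̂_p) + (θ̂_p − θ̂_MA)²),

which inflates the within-model uncertainty by the between-model spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CandidateSet",
    "AveragedEstimate",
    "akaike_weights",
    "model_average",
    "aic",
    "subgroup_selection",
]


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion −2·loglik + 2K."""
    return -2.0 * float(loglik) + 2.0 * int(k)


def akaike_weights(ic) -> np.ndarray:
    """Akaike weights on the probability simplex; invariant to IC shifts."""
    ic = np.asarray(ic, dtype=float)
    if ic.size == 0:
        raise ValueError("empty information-criterion vector")
    if not np.all(np.isfinite(ic)):
        raise ValueError("information criteria must be finite")
    delta = ic - ic.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


@dataclass
class CandidateSet:
    """Per-model IC, focal estimate and its variance."""

    labels: Sequence[str]
    ic: np.ndarray
    theta: np.ndarray
    var: np.ndarray | None = None   # None or NaN entries drop the averaged SE

    def __post_init__(self):
        self.ic = np.asarray(self.ic, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.var is not None:
            self.var = np.asarray(self.var, dtype=float)
        if len(self.labels) < 2:
            raise ValueError("need at least two candidate models")
        if not (len(self.labels) == self.ic.size == self.theta.size):
            raise ValueError("labels, ic and theta must have equal length")


@dataclass
class AveragedEstimate:
    weights: np.ndarray
    theta_ma: float
    se_ma: float | None


def model_average(cands: CandidateSet, weights=None) -> AveragedEstimate:
    """Akaike-weighted average of the candidates' focal estimates.

    ``weights`` overrides the IC-derived weights (e.g. to reproduce a
    published table from its printed weights); they are renormalized.
    If any candidate variance is missing the averaged SE is omitted while
    the averaged estimate is still returned.
    """
    if weights is None:
        w = akaike_weights(cands.ic)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != cands.theta.size or np.any(w < 0):
            raise ValueError("weights must be nonnegative, one per candidate")
        w = w / w.sum()
    theta_ma = float(np.sum(w * cands.theta))
    se_ma = None
    if cands.var is not None and np.all(np.isfinite(cands.var)):
        se_ma = float(np.sum(w * np.sqrt(cands.var + (cands.theta - theta_ma) ** 2)))
    return AveragedEstimate(weights=w, theta_ma=theta_ma, se_ma=se_ma)


def subgroup_selection(aics: Mapping, reasons: Mapping | None = None) -> pd.DataFrame:
    """Rank model families by AIC within each stage subgroup.

    ``aics`` maps ``(stage, family)`` to an AIC value or ``None``/NaN for a
    fit that failed (e.g. a mixed-effects subgroup fit that did not converge
    on a small sample); such cells are kept with their reason rather than
    dropped.  The per-stage argmin over available families is flagged.
    """
    reasons = reasons or {}
    rows = []
    for (stage, family), value in aics.items():
        rows.append(
            {
                "stage": stage,
                "family": str(getattr(family, "value", family)),
                "aic": np.nan if value is None else float(value),
                "note": reasons.get((stage, family), ""),
            }
        )
    table = pd.DataFrame(rows).sort_values(["stage", "family"]).reset_index(drop=True)
    table["best"] = False
    for stage, sub in table.groupby("stage"):
        if sub["aic"].notna().any():
            table.loc[sub["aic"].idxmin(), "best"] = True
    return table
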