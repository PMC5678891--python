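"""Stage contrasts and p-values shared by all three summarization strategies.

A contrast between GOLD stages a and b is Δ = θ̂_a − θ̂_b with
SE = sqrt(se_a² + se_b² − 2·cov); the two-step methods have zero covariance
between stage estimates by construction, while the mixed-effects model
supplies a Wald covariance.  Mixed-effects and meta-analytic contrasts use
the normal reference distribution; the weighted-regression contrast uses a
t reference with m − q residual degrees of freedom.  Raw (unadjusted)
p-values are the default; Holm adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["StageEstimates", "ContrastResult", "contrast", "all_contrasts"]

DEFAULT_PAIRS = ((4, 2), (3, 2), (4, 3))


@dataclass
class StageEstimates:
    """Per-stage estimates of one parameter from one method × family."""

    method: str
    family: str
    param: str
    stages: np.ndarray
    estimates: np.ndarray
    ses: np.ndarray
    cov: np.ndarray | None = None   # q×q; None means independent stages
    df: int | None = None           # t reference when set, else normal

    def __post_init__(self):
        self.stages = np.asarray(self.stages)
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        if self.cov is None:
            self.cov = np.diag(self.ses**2)
        else:
            self.cov = np.asarray(self.cov, dtype=float)

    def index(self, stage) -> int:
        hits = np.nonzero(self.stages == stage)[0]
        if hits.size == 0:
            raise KeyError(f"stage {stage} not present (have {list(self.stages)})")
        return int(hits[0])

    @property
    def pvalues(self) -> np.ndarray:
        """Per-stage p-values for H0: estimate = 0."""
        z = np.abs(self.estimates) / self.ses
        if self.df is None:
            return 2.0 * stats.norm.sf(z)
        return 2.0 * stats.t.sf(z, self.df)


@dataclass
class ContrastResult:
    a: int
    b: int
    estimate: float
    se: float
    statistic: float
    p: float
    df: int | None = None
    p_adjusted: float | None = None

    @property
    def label(self) -> str:
        return f"COPD ({self.a}-{self.b})"


def contrast(est: StageEstimates, a, b) -> ContrastResult:
    """Δ = θ̂_a − θ̂_b with its SE and two-sided p-value."""
    i, j = est.index(a), est.index(b)
    delta = est.estimates[i] - est.estimates[j]
    var = est.cov[i, i] + est.cov[j, j] - 2.0 * est.cov[i, j]
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        stat, p = 0.0, 1.0
    else:
        stat = delta / se
        if est.df is None:
            p = 2.0 * stats.norm.sf(abs(stat))
        else:
            p = 2.0 * stats.t.sf(abs(stat), est.df)
    return ContrastResult(a, b, float(delta), se, float(stat), float(min(p, 1.0)), est.df)


def all_contrasts(est: StageEstimates, pairs=DEFAULT_PAIRS, adjust: str | None = None):
    """The stage contrasts (4−2, 3−2, 4−3 by default), optionally Holm-adjusted."""
    results = [contrast(est, a, b) for a, b in pairs]
    if adjust is not None:
        if adjust.lower() != "holm":
            raise ValueError(f"unsupported adjustment {adjust!r}")
        from statsmodels.stats.multitest import multipletests

        _, padj, _, _ = multipletests([r.p for r in results], method="holm")
        for r, pa in zip(results, padj):
            r.p_adjusted = float(pa)
    return results
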