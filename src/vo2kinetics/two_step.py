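"""Step 2 of the two-step strategies: pooling per-patient estimates.

Each patient contributes an estimate φ̂ᵢ of the focal parameter (default
T½V̇O2) with its standard error σᵢ from the per-patient fit.  Two pooling
models are offered, both with GOLD stage as a cell-means moderator (one θ
per stage, no intercept):

* random-effects meta-regression, φ̂ᵢ = θ_stage(i) + Aᵢ + εᵢ with
  Aᵢ ~ N(0, τ²) and εᵢ ~ N(0, σᵢ²); the within-patient variances are taken
  as known and τ² is estimated by REML (ML and DerSimonian–Laird are
  available).  Inference on θ uses the normal reference.
* weighted regression, εᵢ ~ N(0, σ²σᵢ²) with a multiplicative residual
  variance σ² estimated from the data (weighted RSS/(m−q)); inference uses
  the t reference with m−q degrees of freedom.

The weighted model's point estimates are invariant to rescaling all σᵢ by a
constant; the meta-analytic ones are not, because τ² competes with the σᵢ²
on an absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize

__all__ = ["MetaInput", "SummaryFit", "fit_meta", "fit_weighted"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MetaInput:
    """Per-patient estimates φ̂ᵢ, standard errors σᵢ, and stage labels."""

    phi: np.ndarray
    se: np.ndarray
    stage: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.stage = np.asarray(self.stage)
        if not (self.phi.size == self.se.size == self.stage.size):
            raise ValueError("phi, se and stage must have equal length")
        if self.phi.size == 0:
            raise ValueError("empty input")
        if np.any(self.se <= 0) or not np.all(np.isfinite(self.se)):
            raise ValueError("standard errors must be positive and finite")

    @property
    def m(self) -> int:
        return int(self.phi.size)

    def design(self):
        """Cell-means design: stages (sorted) and the m×q dummy matrix."""
        stages = np.unique(self.stage)
        x = (self.stage[:, None] == stages[None, :]).astype(float)
        return stages, x


@dataclass
class SummaryFit:
    """Per-stage pooled estimates from one pooling method."""

    method: str                 # "meta" or "weighted"
    stages: np.ndarray
    theta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray         # H0: theta = 0
    loglik: float
    aic: float
    m: int
    tau2_hat: float | None = None     # meta only: between-patient heterogeneity
    sigma2_hat: float | None = None   # weighted only: multiplicative residual variance
    df_resid: int | None = None       # weighted only: m − q
    note: str = ""

    def stage_estimate(self, stage) -> tuple[float, float]:
        i = int(np.nonzero(self.stages == stage)[0][0])
        return float(self.theta[i]), float(self.se[i])


def _wls_theta(phi, v, x):
    """Per-stage inverse-variance means given total variances v."""
    w = 1.0 / v
    sw = x.T @ w                       # Σ w per stage (X diagonalizes)
    theta = (x.T @ (w * phi)) / sw
    return theta, sw, w


def _meta_loglik(phi, se2, x, tau2, restricted: bool):
    v = se2 + tau2
    theta, sw, w = _wls_theta(phi, v, x)
    resid = phi - x @ theta
    m, q = x.shape
    ll = -0.5 * (m * _LOG2PI + np.sum(np.log(v)) + np.sum(w * resid**2))
    if restricted:
        ll += 0.5 * q * _LOG2PI
        ll -= 0.5 * np.sum(np.log(sw))
    return ll, theta, sw


def _dersimonian_laird(phi, se2, x):
    w0 = 1.0 / se2
    theta, sw, _ = _wls_theta(phi, se2, x)
    resid = phi - x @ theta
    q_stat = np.sum(w0 * resid**2)
    m, q = x.shape
    # tr(W) − tr((XᵀWX)⁻¹ XᵀW²X) for the cell-means design
    c = np.sum(w0) - np.sum((x.T @ w0**2) / sw)
    if c <= 0:
        return 0.0
    return max(0.0, (q_stat - (m - q)) / c)


def fit_meta(inp: MetaInput, method: str = "reml", tau2: float | None = None) -> SummaryFit:
    """Random-effects meta-regression with stage cell means.

    ``tau2`` fixes the heterogeneity variance (used for oracle checks and
    limits); otherwise it is estimated by ``method`` in
    {"reml", "ml", "dl"}.  Standard errors come from the weighted
    information 1/√Σwᵢ per stage; p-values use the normal reference.
    AIC is −2·loglik + 2(q+1) on the fitting likelihood.
    """
    method = method.lower()
    if method not in {"reml", "ml", "dl"}:
        raise ValueError(f"unknown method {method!r}")
    stages, x = inp.design()
    m, q = x.shape
    se2 = inp.se**2
    restricted = method == "reml"

    note = ""
    if tau2 is not None:
        if tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        tau2_hat = float(tau2)
    elif m <= q:
        # one patient per stage: no replication, heterogeneity inestimable
        tau2_hat = 0.0
        note = "tau2 inestimable (m <= q); fixed at 0"
    elif method == "dl":
        tau2_hat = _dersimonian_laird(inp.phi, se2, x)
    else:
        ub = max(10.0 * float(np.var(inp.phi)), 10.0 * float(se2.max()), 1.0)

        def neg(t2):
            return -_meta_loglik(inp.phi, se2, x, t2, restricted)[0]

        res = optimize.minimize_scalar(neg, bounds=(0.0, ub), method="bounded",
                                       options={"xatol": 1e-8})
        tau2_hat = float(res.x) if neg(res.x) <= neg(0.0) else 0.0

    ll, theta, sw = _meta_loglik(inp.phi, se2, x, tau2_hat, restricted)
    se_theta = 1.0 / np.sqrt(sw)
    from scipy.stats import norm

    pvals = 2.0 * norm.sf(np.abs(theta) / se_theta)
    aic = -2.0 * ll + 2.0 * (q + 1)
    return SummaryFit(
        method="meta", stages=stages, theta=theta, se=se_theta, pvalues=pvals,
        loglik=float(ll), aic=float(aic), m=m, tau2_hat=tau2_hat, note=note,
    )


def fit_weighted(inp: MetaInput) -> SummaryFit:
    """Weighted least squares of φ̂ on stage dummies with weights 1/σᵢ².

    The multiplicative residual variance σ̂² = weighted RSS/(m−q) scales the
    standard errors; p-values use the t reference with m−q df.
    """
    stages, x = inp.design()
    m, q = x.shape
    if m <= q:
        raise ValueError(f"need more patients ({m}) than stages ({q})")
    model = sm.WLS(inp.phi, x, weights=1.0 / inp.se**2)
    res = model.fit()
    theta = np.asarray(res.params, dtype=float)
    se_theta = np.asarray(res.bse, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)  # t with m−q df
    sigma2_hat = float(res.scale)                 # weighted RSS/(m−q)
    ll = float(res.llf)
    aic = -2.0 * ll + 2.0 * (q + 1)
    return SummaryFit(
        method="weighted", stages=stages, theta=theta, se=se_theta, pvalues=pvals,
        loglik=ll, aic=float(aic), m=m, sigma2_hat=sigma2_hat, df_resid=m - q,
    )
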