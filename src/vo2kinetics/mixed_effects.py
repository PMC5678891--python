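"""Nonlinear mixed-effects fit of one kinetic family to a whole cohort.

Model: y_ij = V̇O2(t_ij; β_i) + ε_ij, ε_ij ~ N(0, σ²) i.i.d., with
patient-specific parameters β_i = A_i β + B_i b_i.  A_i is the stage
cell-means design (GOLD stages 2/3/4 × 6 curve parameters → 18 fixed
effects) and b_i ~ N(0, G) are random effects on the four recovery
parameters (vo2_ss, t_half, tau2, vo2_rec).  G is diagonal by default
(a full covariance via a log-Cholesky parameterization is available, but
four correlated random effects on a 61-patient cohort is fragile).

Estimation alternates, in the Lindstrom–Bates fashion, between

1. a penalized nonlinear least-squares (PNLS) step: minimize
   Σ_i ||y_i − f_i(β, b_i)||² + b_iᵀ D⁻¹ b_i jointly over β and all b_i,
   where G = σ²D (D the relative covariance of the random effects); and
2. an LME step: linearize f about the current (β̂, b̂_i) and maximize the
   profiled marginal Gaussian likelihood of the resulting linear
   mixed model over the variance parameters, with β and σ² profiled out.

The marginal log-likelihood reported is the linearized ML criterion at
convergence; AIC counts K = 18 fixed effects + the G parameters + σ².
Wald covariance for β comes from the GLS information Σ X_iᵀV_i⁻¹X_i.
Non-convergence (including the single-stage subgroup fits that are prone
to it on small samples) is reported through the ``converged`` flag and
``notes`` — a failed fit is a first-class result, not an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import least_squares

from .models import PARAM_NAMES, KineticParams, ModelFamily, evaluate, gradient
from .inference import StageEstimates
from .patient_fit import FitResult, auto_init, fit_cohort, _effective_lam
from .preprocessing import PatientSeries

__all__ = ["NlmeSpec", "NlmeFit", "fit_nlme", "stage_estimates"]

DEFAULT_RANDOM = ("vo2_ss", "t_half", "tau2", "vo2_rec")
_LOG2PI = np.log(2.0 * np.pi)
_ETA_MIN, _ETA_MAX = -16.0, 10.0   # bounds on log relative variances


@dataclass
class NlmeSpec:
    """Configuration of one cohort-level mixed-effects fit."""

    family: ModelFamily
    random_params: tuple[str, ...] = DEFAULT_RANDOM
    g_structure: str = "diagonal"   # or "full"
    max_outer: int = 200
    outer_tol: float = 1e-6         # relative marginal-loglik change

    def __post_init__(self):
        self.family = ModelFamily.coerce(self.family)
        unknown = set(self.random_params) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown random parameters: {sorted(unknown)}")
        if self.g_structure not in {"diagonal", "full"}:
            raise ValueError("g_structure must be 'diagonal' or 'full'")


@dataclass
class NlmeFit:
    """Result of one cohort fit."""

    family: ModelFamily
    stages: np.ndarray              # sorted unique stages, length S
    beta: np.ndarray                # (6, S) fixed effects, PARAM_NAMES rows
    beta_se: np.ndarray             # (6, S)
    beta_cov: np.ndarray            # (6S, 6S), raveled row-major (param, stage)
    G_hat: np.ndarray               # (k, k) random-effect covariance
    sigma2_hat: float
    loglik: float
    aic: float
    n_patients: int
    n_obs: int
    converged: bool
    n_iter: int
    random_params: tuple[str, ...]
    loglik_path: list = field(default_factory=list)
    notes: list = field(default_factory=list)
    b_hat: np.ndarray | None = None  # (m, k) random-effect modes

    def stage_index(self, stage) -> int:
        hits = np.nonzero(self.stages == stage)[0]
        if hits.size == 0:
            raise KeyError(f"stage {stage} not in fit")
        return int(hits[0])

    def param_block(self, param: str):
        """Estimates, SEs and covariance of one parameter across stages."""
        p = PARAM_NAMES.index(param)
        s = self.stages.size
        idx = np.arange(p * s, (p + 1) * s)
        return (
            self.beta[p, :].copy(),
            self.beta_se[p, :].copy(),
            self.beta_cov[np.ix_(idx, idx)].copy(),
        )


class _Cohort:
    """Pre-extracted arrays for one aligned cohort."""

    def __init__(self, series, random_params, family):
        if len(series) == 0:
            raise ValueError("empty cohort")
        lam_max = {s.lam_max for s in series}
        if None in lam_max:
            raise ValueError("cohort must be aligned (run align_to_lam_max first)")
        if len(lam_max) > 1:
            raise ValueError("inconsistent lam_max across patients")
        self.lam = float(lam_max.pop())
        self.family = family
        self.series = list(series)
        self.stages = np.unique([s.stage for s in series])
        self.stage_idx = np.array(
            [int(np.nonzero(self.stages == s.stage)[0][0]) for s in series]
        )
        self.rand_idx = np.array([PARAM_NAMES.index(p) for p in random_params], dtype=int)
        self.m = len(series)
        self.k = self.rand_idx.size
        self.S = self.stages.size
        self.n_i = np.array([s.n_obs for s in series])
        self.N = int(self.n_i.sum())
        counts = np.bincount(self.stage_idx, minlength=self.S)
        if np.any(counts < 2) and self.m > self.S:
            pass  # single-patient stages are allowed but fragile; caller decides
        self.template = KineticParams(
            300.0, 1000.0, 400.0, 30.0, -2.0, 120.0, self.lam, self.lam
        )

    def patient_params(self, beta, b, i) -> KineticParams:
        theta = beta[:, self.stage_idx[i]].copy()
        if self.k:
            theta[self.rand_idx] += b[i]
        # the optimizer may wander through invalid territory; keep the two
        # positive-only time parameters evaluable (floor, no validation)
        theta[3] = max(theta[3], 0.5)   # tau1
        theta[5] = max(theta[5], 1.0)   # t_half
        return self.template.with_free_values(theta)

    def predict(self, beta, b, i):
        return evaluate(
            self.series[i].times, self.patient_params(beta, b, i), self.family,
            validate=False,
        )

    def grad(self, beta, b, i):
        return gradient(
            self.series[i].times, self.patient_params(beta, b, i), self.family,
            validate=False,
        )


def _pnls(cohort: _Cohort, beta0, b0, d_inv_sqrt):
    """Joint penalized least squares over (β, b) given D^{-1/2} penalty."""
    m, k, S = cohort.m, cohort.k, cohort.S
    nb = 6 * S

    def unpack(x):
        beta = x[:nb].reshape(6, S)
        b = x[nb:].reshape(m, k) if k else np.zeros((m, 0))
        return beta, b

    def resid(x):
        beta, b = unpack(x)
        parts = [
            cohort.predict(beta, b, i) - cohort.series[i].vo2 for i in range(m)
        ]
        if k:
            parts.append((b @ d_inv_sqrt.T).ravel())
        return np.concatenate(parts)

    n_rows = cohort.N + m * k
    n_cols = nb + m * k

    def jac(x):
        beta, b = unpack(x)
        out = np.zeros((n_rows, n_cols))
        row = 0
        for i in range(m):
            g = cohort.grad(beta, b, i)
            n = g.shape[0]
            si = cohort.stage_idx[i]
            for p in range(6):
                out[row:row + n, p * S + si] = g[:, p]
            if k:
                cols = nb + i * k
                out[row:row + n, cols:cols + k] = g[:, cohort.rand_idx]
            row += n
        if k:
            for i in range(m):
                out[row:row + k, nb + i * k:nb + (i + 1) * k] = d_inv_sqrt
                row += k
        return out

    x0 = np.concatenate([beta0.ravel(), b0.ravel()]) if k else beta0.ravel()
    sol = least_squares(resid, x0, jac=jac, method="trf",
                        ftol=1e-10, xtol=1e-12, gtol=1e-10, max_nfev=200)
    beta, b = unpack(sol.x)
    return beta, b, sol


def _linearize(cohort: _Cohort, beta, b):
    """Per-patient cross-products of the linearized mixed model."""
    S, k = cohort.S, cohort.k
    nb = 6 * S
    stats = []
    for i in range(cohort.m):
        g = cohort.grad(beta, b, i)
        si = cohort.stage_idx[i]
        x = np.zeros((g.shape[0], nb))
        for p in range(6):
            x[:, p * S + si] = g[:, p]
        z = g[:, cohort.rand_idx] if k else np.zeros((g.shape[0], 0))
        f = cohort.predict(beta, b, i)
        w = cohort.series[i].vo2 - f + x @ beta.ravel()
        if k:
            w = w + z @ b[i]
        stats.append(
            dict(
                ZtZ=z.T @ z, ZtX=z.T @ x, Ztw=z.T @ w,
                XtX=x.T @ x, Xtw=x.T @ w, wtw=float(w @ w),
            )
        )
    return stats


def _chol_from_eta(eta, k, structure):
    """Lower-triangular L with D = L Lᵀ from the variance parameterization."""
    if structure == "diagonal":
        return np.diag(np.exp(0.5 * np.clip(eta, _ETA_MIN, _ETA_MAX)))
    L = np.zeros((k, k))
    pos = 0
    for j in range(k):
        L[j, j] = np.exp(0.5 * np.clip(eta[pos], _ETA_MIN, _ETA_MAX))
        pos += 1
        for r in range(j + 1, k):
            L[r, j] = eta[pos]
            pos += 1
    return L


def _profiled_ml(stats, L, nb, N):
    """Profiled marginal ML of the linearized model for fixed L (D = LLᵀ).

    Returns (loglik, beta, sigma2, info) with info = Σ XᵀV⁻¹X.
    """
    k = L.shape[0]
    A_sum = np.zeros((nb, nb))
    c_sum = np.zeros(nb)
    q_sum = 0.0
    logdet = 0.0
    caches = []
    for st in stats:
        if k:
            A_i = np.eye(k) + L.T @ st["ZtZ"] @ L
            cf = cho_factor(A_i, lower=True)
            logdet += 2.0 * np.sum(np.log(np.diag(cf[0])))
            LZX = L.T @ st["ZtX"]
            LZw = L.T @ st["Ztw"]
            s1 = cho_solve(cf, LZX)
            s2 = cho_solve(cf, LZw)
            A_sum += st["XtX"] - LZX.T @ s1
            c_sum += st["Xtw"] - LZX.T @ s2
            q_sum += st["wtw"] - LZw @ s2
            caches.append(cf)
        else:
            A_sum += st["XtX"]
            c_sum += st["Xtw"]
            q_sum += st["wtw"]
            caches.append(None)
    beta = np.linalg.solve(A_sum, c_sum)
    rss = max(q_sum - c_sum @ beta, 1e-12)
    sigma2 = rss / N
    ll = -0.5 * (N * (_LOG2PI + np.log(sigma2) + 1.0) + logdet)
    return ll, beta, sigma2, A_sum, caches


def _init_from_fits(cohort: _Cohort, fits: list[FitResult]):
    """Fixed effects from per-patient medians by stage; D from their spread."""
    S = cohort.S
    beta0 = np.zeros((6, S))
    usable = [f for f in fits if f.converged] or fits
    sigma2_0 = float(np.median([f.sigma2 for f in usable]))
    for si, stage in enumerate(cohort.stages):
        sub = [f for f in usable if f.stage == stage] or usable
        for p, name in enumerate(PARAM_NAMES):
            beta0[p, si] = np.median([f.estimate(name) for f in sub])
    stage_col = {stage: si for si, stage in enumerate(cohort.stages)}
    d0 = np.ones(cohort.k)
    for j, p in enumerate(cohort.rand_idx):
        name = PARAM_NAMES[p]
        resid = [f.estimate(name) - beta0[p, stage_col[f.stage]] for f in usable]
        var = float(np.var(resid)) if len(resid) > 1 else sigma2_0
        d0[j] = max(var / max(sigma2_0, 1e-8), 1e-4)
    return beta0, d0, sigma2_0


def fit_nlme(
    cohort_series,
    spec: NlmeSpec,
    per_patient: list[FitResult] | None = None,
) -> NlmeFit:
    """Fit one family to an aligned cohort by alternating PNLS/LME steps.

    ``per_patient`` supplies existing single-patient fits of the same family
    for initialization; when omitted they are computed internally.
    """
    cohort = _Cohort(cohort_series, spec.random_params, spec.family)
    m, k, S, N = cohort.m, cohort.k, cohort.S, cohort.N
    nb = 6 * S
    notes: list[str] = []

    if per_patient is None:
        per_patient = fit_cohort(cohort.series, [spec.family])
    else:
        per_patient = [f for f in per_patient if f.family == spec.family]
        if len(per_patient) != m:
            per_patient = fit_cohort(cohort.series, [spec.family])
    beta, d0, sigma2 = _init_from_fits(cohort, per_patient)
    b = np.zeros((m, k))

    if spec.g_structure == "diagonal" or k == 0:
        eta = np.log(np.clip(d0, 1e-6, None)) if k else np.zeros(0)
        structure = "diagonal"
    else:
        structure = "full"
        eta = np.zeros(k * (k + 1) // 2)
        pos = 0
        for j in range(k):
            eta[pos] = np.log(max(d0[j], 1e-6))
            pos += 1 + (k - j - 1)

    # no random effects: a single PNLS pass is pooled per-stage NLS
    if k == 0:
        beta, b, sol = _pnls(cohort, beta, b, np.zeros((0, 0)))
        stats = _linearize(cohort, beta, b)
        ll, beta_vec, sigma2, A_sum, _ = _profiled_ml(stats, np.zeros((0, 0)), nb, N)
        beta = beta_vec.reshape(6, S)
        cov = sigma2 * np.linalg.inv(A_sum)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf)).reshape(6, S)
        return NlmeFit(
            spec.family, cohort.stages, beta, se, cov, np.zeros((0, 0)),
            float(sigma2), float(ll), aic=-2.0 * ll + 2.0 * (nb + 1),
            n_patients=m, n_obs=N, converged=bool(sol.success), n_iter=1,
            random_params=(), loglik_path=[float(ll)], notes=notes,
            b_hat=b,
        )

    ll_old = -np.inf
    ll = -np.inf
    converged = False
    ll_path: list[float] = []
    A_sum = np.eye(nb)
    it = 0
    for it in range(1, spec.max_outer + 1):
        L = _chol_from_eta(eta, k, structure)
        # penalty factor D^{-1/2}: inverse of L (lower triangular)
        d_inv_sqrt = np.linalg.inv(L)
        beta, b, sol = _pnls(cohort, beta, b, d_inv_sqrt)
        stats = _linearize(cohort, beta, b)

        def neg(e):
            Le = _chol_from_eta(e, k, structure)
            return -_profiled_ml(stats, Le, nb, N)[0]

        if structure == "diagonal":
            bounds = [(_ETA_MIN, _ETA_MAX)] * k
        else:
            bounds = []
            pos = 0
            for j in range(k):
                bounds.append((_ETA_MIN, _ETA_MAX))
                pos += 1
                bounds.extend([(-1e3, 1e3)] * (k - j - 1))
        res = optimize.minimize(neg, eta, method="L-BFGS-B", bounds=bounds)
        eta = res.x
        L = _chol_from_eta(eta, k, structure)
        ll, beta_vec, sigma2, A_sum, caches = _profiled_ml(stats, L, nb, N)
        beta = beta_vec.reshape(6, S)
        # BLUP update of the random-effect modes
        for i, st in enumerate(stats):
            Ztr = st["Ztw"] - st["ZtX"] @ beta_vec
            b[i] = L @ cho_solve(caches[i], L.T @ Ztr)
        ll_path.append(float(ll))
        if np.isfinite(ll_old) and abs(ll - ll_old) <= spec.outer_tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll

    if not converged:
        notes.append(
            f"did not converge in {spec.max_outer} outer iterations; "
            "estimates from the last iterate are flagged unusable"
        )
    D = L @ L.T
    G_hat = sigma2 * D
    if structure == "diagonal":
        near_zero = [
            spec.random_params[j]
            for j in range(k)
            if eta[j] <= _ETA_MIN + 1e-6
        ]
        if near_zero:
            notes.append(f"variance component ~0 (boundary) for: {near_zero}")

    cov = sigma2 * np.linalg.inv(A_sum)
    se = np.sqrt(np.clip(np.diag(cov), 0, np.inf)).reshape(6, S)
    n_gpar = k if structure == "diagonal" else k * (k + 1) // 2
    return NlmeFit(
        spec.family, cohort.stages, beta, se, cov, G_hat, float(sigma2),
        float(ll), aic=-2.0 * ll + 2.0 * (nb + n_gpar + 1),
        n_patients=m, n_obs=N, converged=converged, n_iter=it,
        random_params=tuple(spec.random_params), loglik_path=ll_path,
        notes=notes, b_hat=b,
    )


def stage_estimates(fit: NlmeFit, param: str = "t_half") -> StageEstimates:
    """Per-stage estimates of one parameter with Wald covariance (z reference)."""
    if param not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {param!r}")
    est, se, cov = fit.param_block(param)
    return StageEstimates(
        method="mixed",
        family=fit.family.value,
        param=param,
        stages=fit.stages,
        estimates=est,
        ses=se,
        cov=cov,
        df=None,
    )
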