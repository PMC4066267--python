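"""Longitudinal count-model ladder: PLME, NBLME and ZINBLME.

Three families of mixed-effects models for per-phylotype read counts, each
with a subject-level random intercept b ~ N(0, sigma_b^2) on the (log-link)
mean and a fixed offset log(total reads) so the models describe relative
rather than absolute abundance:

* PLME   — Poisson:             y_ij | b_i ~ Poisson(mu_ij)
* NBLME  — negative binomial:   y_ij | b_i ~ NB(mu_ij, k)    (Var = mu + mu^2/k)
* ZINBLME — zero-inflated NB:   y_ij | b_i ~ pi * delta_0 + (1-pi) * NB(mu_ij, k)

with mu_ij = exp(x_ij' beta + offset_ij + b_i).  The random intercept acts
only on the NB/Poisson mean, never on the zero-inflation probability, and
the zero-inflation component is intercept-only.

The marginal likelihood integrates the random intercept out per subject by
adaptive Gauss–Hermite quadrature (centered and scaled at the per-subject
posterior mode).  Maximum likelihood uses quasi-Newton optimization on an
unconstrained parameterization (log sigma_b, log k, logit pi), with a
moment-based start from a Poisson GLM plus optional jittered restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import norm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "marginal_loglik",
    "fit",
    "aic",
    "wald",
    "wald_linear",
    "FAMILIES",
]

FAMILIES = ("PLME", "NBLME", "ZINBLME")

_SIGMA_TINY = 1e-6  # below this the random effect is treated as degenerate
_ETA_CLIP = 35.0  # cap on the linear predictor; exp(35) ~ 1.6e15


@dataclass
class ModelSpec:
    """Design for one phylotype model: fixed effects, offset, subject map."""

    family: str
    X: np.ndarray  # (n, p) fixed design including intercept column
    offset: np.ndarray  # (n,) natural-log total reads
    subjects: np.ndarray  # (n,) subject identifiers (any hashable dtype)
    colnames: tuple[str, ...] = ()
    quad_points: int = 25

    # derived, filled in __post_init__
    order: np.ndarray = field(init=False, repr=False)
    starts: np.ndarray = field(init=False, repr=False)
    n_subjects: int = field(init=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        self.X = np.asarray(self.X, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        n = self.X.shape[0]
        if self.offset.shape != (n,) or len(self.subjects) != n:
            raise ValueError("X, offset and subjects must have matching length")
        if not np.all(np.isfinite(self.offset)) or not np.all(np.isfinite(self.X)):
            raise ValueError("design and offset must be finite")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed design matrix is column-rank deficient")
        if not self.colnames:
            self.colnames = tuple(f"x{j}" for j in range(self.X.shape[1]))
        uniq, subj_codes = np.unique(np.asarray(self.subjects), return_inverse=True)
        self.order = np.argsort(subj_codes, kind="stable")
        sorted_codes = subj_codes[self.order]
        self.starts = np.flatnonzero(np.r_[True, np.diff(sorted_codes) != 0])
        self.n_subjects = len(uniq)
        self._X_s = self.X[self.order]
        self._off_s = self.offset[self.order]
        self._subj_s = sorted_codes
        self._z, self._w = hermgauss(self.quad_points)
        self._logw = np.log(self._w)
        # warm start for the per-subject posterior-mode search; successive
        # optimizer evaluations move the modes only slightly
        self._b_warm = np.zeros(self.n_subjects)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_params(self) -> int:
        # beta + sigma_b (+ k) (+ pi)
        return self.n_fixed + 1 + (self.family != "PLME") + (self.family == "ZINBLME")

    def sort_counts(self, counts: np.ndarray) -> np.ndarray:
        y = np.asarray(counts)
        if y.shape != (self.n_obs,):
            raise ValueError("counts length does not match design")
        if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
            raise ValueError("counts must be nonnegative integers")
        return y[self.order].astype(float)

    def unpack(self, params: np.ndarray):
        """Split a natural-scale parameter vector into (beta, sigma_b, k, pi)."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"expected {self.n_params} parameters for {self.family}, got {params.shape}"
            )
        p = self.n_fixed
        beta, sigma = params[:p], params[p]
        k = params[p + 1] if self.family != "PLME" else None
        pi = params[p + 2] if self.family == "ZINBLME" else None
        if sigma < 0:
            raise ValueError("sigma_b must be >= 0")
        if k is not None and k <= 0:
            raise ValueError("NB dispersion k must be > 0")
        if pi is not None and not 0 <= pi < 1:
            raise ValueError("zero-inflation pi must be in [0, 1)")
        return beta, sigma, k, pi


def _nb_logpmf(y, eta, k):
    log_k_mu = np.logaddexp(np.log(k), eta)
    return (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1)
        + k * (np.log(k) - log_k_mu)
        + y * (eta - log_k_mu)
    )


def _obs_loglik(y, eta, family, k, pi):
    """Per-observation conditional log-density given the random effect."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if family == "PLME":
        return y * eta - np.exp(eta) - gammaln(y + 1)
    ll = _nb_logpmf(y, eta, k)
    if family == "NBLME" or pi in (None, 0.0):
        return ll
    is_zero = y == 0
    out = np.log1p(-pi) + ll
    if np.any(is_zero):
        zero_ll = np.logaddexp(np.log(pi), np.log1p(-pi) + ll)
        out = np.where(is_zero, zero_ll, out)
    return out


def _obs_derivs(y, eta, family, k, pi):
    """First and second derivatives of the conditional log-density w.r.t. b."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    if family == "PLME":
        return y - mu, -mu
    t = k * mu / (k + mu)  # = -d/db log NB(0)
    d1 = k * (y - mu) / (k + mu)
    d2 = -mu * k * (k + y) / (k + mu) ** 2
    if family == "NBLME" or pi in (None, 0.0):
        return d1, d2
    is_zero = y == 0
    if np.any(is_zero):
        log_s = k * (np.log(k) - np.logaddexp(np.log(k), eta))  # log NB(0)
        # w = P(structural-zero complement | y=0): weight of the NB branch
        w = 1.0 / (1.0 + pi / ((1.0 - pi) * np.exp(np.clip(log_s, -700, 0))))
        d1_zero = -w * t
        d2_zero = w * (1.0 - w) * t**2 - w * (k**2 * mu / (k + mu) ** 2)
        d1 = np.where(is_zero, d1_zero, d1)
        d2 = np.where(is_zero, d2_zero, d2)
    return d1, d2


def _segment_sum(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(values, starts, axis=0)


def marginal_loglik(spec: ModelSpec, params: np.ndarray, counts: np.ndarray) -> float:
    """Marginal log-likelihood with the subject random intercept integrated out.

    For each subject the integral of the conditional likelihood against the
    N(0, sigma_b^2) random-intercept density is evaluated by adaptive
    Gauss–Hermite quadrature centered at the subject's posterior mode.
    Raises on a non-finite result, naming the offending subject.
    """
    beta, sigma, k, pi = spec.unpack(params)
    y = spec.sort_counts(counts)
    eta0 = spec._X_s @ beta + spec._off_s

    if sigma < _SIGMA_TINY:
        ll = float(np.sum(_obs_loglik(y, eta0, spec.family, k, pi)))
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood at sigma_b = 0")
        return ll

    starts = spec.starts
    S = spec.n_subjects
    subj = spec._subj_s

    # --- posterior mode of b per subject (damped Newton, warm-started) ---
    b = spec._b_warm.copy()
    inv_s2 = 1.0 / sigma**2
    for _ in range(50):
        d1, d2 = _obs_derivs(y, eta0 + b[subj], spec.family, k, pi)
        grad = _segment_sum(d1, starts) - b * inv_s2
        hess = _segment_sum(d2, starts) - inv_s2
        hess = np.minimum(hess, -inv_s2 * 1e-8 - 1e-12)
        step = np.clip(-grad / hess, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    d1, d2 = _obs_derivs(y, eta0 + b[subj], spec.family, k, pi)
    hess = _segment_sum(d2, starts) - inv_s2
    hess = np.minimum(hess, -inv_s2 * 1e-8 - 1e-12)
    tau = 1.0 / np.sqrt(-hess)
    spec._b_warm = b

    # --- adaptive Gauss–Hermite nodes around the mode ---
    z, logw = spec._z, spec._logw
    nodes = b[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]  # (S, Q)
    eta_nodes = eta0[:, None] + nodes[subj]  # (n, Q)
    ll_obs = _obs_loglik(y[:, None], eta_nodes, spec.family, k, pi)
    ll_subj = _segment_sum(ll_obs, starts)  # (S, Q)
    log_prior = -0.5 * nodes**2 * inv_s2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    h = ll_subj + log_prior + z[None, :] ** 2 + logw[None, :]
    hmax = h.max(axis=1)
    ll_per_subject = (
        np.log(np.sqrt(2.0) * tau)
        + hmax
        + np.log(np.exp(h - hmax[:, None]).sum(axis=1))
    )
    if not np.all(np.isfinite(ll_per_subject)):
        bad = int(np.flatnonzero(~np.isfinite(ll_per_subject))[0])
        raise FloatingPointError(f"non-finite marginal likelihood for subject index {bad}")
    return float(ll_per_subject.sum())


@dataclass
class ModelFit:
    """One fitted PLME/NBLME/ZINBLME model."""

    family: str
    beta: np.ndarray  # natural-log scale
    sigma_b: float
    dispersion: Optional[float]  # NB size k; None for PLME
    zi_prob: Optional[float]  # pi; None unless ZINBLME
    loglik: float
    n_obs: int
    n_params: int
    se: np.ndarray  # SE per natural-scale parameter (beta..., sigma_b, k, pi)
    converged: bool
    boundary: bool = False
    colnames: tuple[str, ...] = ()
    message: str = ""
    cov: Optional[np.ndarray] = None  # natural-scale parameter covariance

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def params(self) -> np.ndarray:
        extra = [self.sigma_b]
        if self.family != "PLME":
            extra.append(self.dispersion)
        if self.family == "ZINBLME":
            extra.append(self.zi_prob)
        return np.r_[self.beta, extra]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "beta": list(map(float, self.beta)),
            "sigma_b": float(self.sigma_b),
            "dispersion": None if self.dispersion is None else float(self.dispersion),
            "zi_prob": None if self.zi_prob is None else float(self.zi_prob),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "se": [None if not np.isfinite(s) else float(s) for s in self.se],
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "boundary": self.boundary,
            "colnames": list(self.colnames),
            "message": self.message,
        }


def aic(fit_result: ModelFit) -> float:
    """Akaike Information Criterion, 2*n_params - 2*loglik (smaller is better)."""
    return fit_result.aic


def _to_unconstrained(spec: ModelSpec, params: np.ndarray) -> np.ndarray:
    beta, sigma, k, pi = spec.unpack(params)
    out = [beta, [np.log(max(sigma, 1e-8))]]
    if k is not None:
        out.append([np.log(k)])
    if pi is not None:
        pi = min(max(pi, 1e-6), 1 - 1e-6)
        out.append([np.log(pi / (1 - pi))])
    return np.concatenate(out)


def _from_unconstrained(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    p = spec.n_fixed
    vals = [theta[:p], [np.exp(theta[p])]]
    if spec.family != "PLME":
        vals.append([np.exp(theta[p + 1])])
    if spec.family == "ZINBLME":
        vals.append([1.0 / (1.0 + np.exp(-theta[p + 2]))])
    return np.concatenate(vals)


def _moment_start(spec: ModelSpec, counts: np.ndarray) -> np.ndarray:
    """Poisson-GLM beta, method-of-moments k, excess-zero pi, sigma_b = 0.5."""
    y = np.asarray(counts, dtype=float)
    try:
        glm = sm.GLM(y, spec.X, family=sm.families.Poisson(), offset=spec.offset)
        res = glm.fit(maxiter=50, tol=1e-8)
        beta = np.asarray(res.params, dtype=float)
        mu = res.mu
    except Exception:
        rate = max(y.sum(), 1.0) / np.exp(spec.offset).sum()
        beta = np.zeros(spec.n_fixed)
        beta[0] = np.log(rate)
        mu = np.exp(spec.X @ beta + spec.offset)
    parts = [beta, [0.5]]
    if spec.family != "PLME":
        excess = np.mean((y - mu) ** 2 - mu)
        k = np.mean(mu**2) / excess if excess > 0 else 10.0
        parts.append([float(np.clip(k, 0.05, 100.0))])
    if spec.family == "ZINBLME":
        zero_frac = np.mean(y == 0)
        parts.append([float(np.clip(zero_frac * 0.5 + 0.01, 0.01, 0.9))])
    return np.concatenate(parts)


def _numeric_se(spec: ModelSpec, params: np.ndarray, counts: np.ndarray):
    """SEs and covariance from the inverse observed information
    (central-difference Hessian on the natural scale).  Parameters at their
    boundary are held fixed and get SE = nan."""
    params = np.asarray(params, dtype=float)
    m = len(params)
    p = spec.n_fixed
    free = np.ones(m, dtype=bool)
    if params[p] < 1e-4:  # sigma_b at zero boundary
        free[p] = False
    if spec.family == "ZINBLME" and (params[p + 2] < 1e-4 or params[p + 2] > 1 - 1e-4):
        free[p + 2] = False
    idx = np.flatnonzero(free)
    steps = np.maximum(1e-4, 1e-4 * np.abs(params))

    def f(q):
        full = params.copy()
        full[idx] = q
        # keep inside the domain
        full[p] = max(full[p], 0.0)
        if spec.family != "PLME":
            full[p + 1] = max(full[p + 1], 1e-8)
        if spec.family == "ZINBLME":
            full[p + 2] = min(max(full[p + 2], 0.0), 1 - 1e-9)
        return marginal_loglik(spec, full, counts)

    q0 = params[idx]
    h = steps[idx]
    nf = len(idx)
    H = np.zeros((nf, nf))
    f0 = f(q0)
    for a in range(nf):
        for bidx in range(a, nf):
            ea = np.zeros(nf)
            eb = np.zeros(nf)
            ea[a] = h[a]
            eb[bidx] = h[bidx]
            if a == bidx:
                val = (f(q0 + ea) - 2 * f0 + f(q0 - ea)) / h[a] ** 2
            else:
                val = (
                    f(q0 + ea + eb) - f(q0 + ea - eb) - f(q0 - ea + eb) + f(q0 - ea - eb)
                ) / (4 * h[a] * h[bidx])
            H[a, bidx] = H[bidx, a] = val
    se = np.full(m, np.nan)
    cov_full = np.full((m, m), np.nan)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)
    diag = np.diag(cov)
    pos = diag > 0
    se[idx[pos]] = np.sqrt(diag[pos])
    cov_full[np.ix_(idx, idx)] = cov
    return se, cov_full


def fit(
    spec: ModelSpec,
    counts: np.ndarray,
    n_restarts: int = 3,
    restart_seed: int = 0,
    compute_se: bool = True,
    maxiter: int = 300,
) -> ModelFit:
    """Maximum-likelihood fit of one model family.

    Quasi-Newton (L-BFGS-B) search on the unconstrained parameterization,
    starting from a moment-based Poisson-GLM start plus ``n_restarts``
    jittered restarts; the best converged optimum is kept.  A fit where all
    starts fail is returned with ``converged=False`` rather than raising.
    """
    if len(np.unique(np.asarray(spec.subjects))) < 2:
        raise ValueError("need at least 2 subjects for a mixed model")
    y = np.asarray(counts, dtype=float)
    start_nat = _moment_start(spec, y)
    theta0 = _to_unconstrained(spec, start_nat)
    rng = np.random.default_rng(restart_seed)
    starts = [theta0]
    for _ in range(n_restarts):
        starts.append(theta0 + rng.normal(0.0, 0.4, size=theta0.shape))

    p = spec.n_fixed
    bounds = [(None, None)] * p + [(np.log(1e-6), np.log(20.0))]
    if spec.family != "PLME":
        bounds.append((np.log(1e-4), np.log(1e5)))
    if spec.family == "ZINBLME":
        bounds.append((-9.0, 9.0))

    def nll(theta):
        try:
            return -marginal_loglik(spec, _from_unconstrained(spec, theta), y)
        except FloatingPointError:
            return 1e12

    best = None
    message = ""
    for theta_start in starts:
        try:
            res = minimize(
                nll,
                theta_start,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
            )
        except (FloatingPointError, OverflowError) as exc:  # pragma: no cover
            message = str(exc)
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            message = "non-finite objective"
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res

    if best is None:
        nan = np.full(spec.n_params, np.nan)
        return ModelFit(
            family=spec.family,
            beta=np.full(p, np.nan),
            sigma_b=np.nan,
            dispersion=np.nan if spec.family != "PLME" else None,
            zi_prob=np.nan if spec.family == "ZINBLME" else None,
            loglik=-np.inf,
            n_obs=spec.n_obs,
            n_params=spec.n_params,
            se=nan,
            converged=False,
            colnames=spec.colnames,
            message=message or "all starts failed",
        )

    params = _from_unconstrained(spec, best.x)
    beta, sigma, k, pi = spec.unpack(params)
    boundary = sigma <= 1.1e-6 or (pi is not None and (pi < 1e-4 or pi > 1 - 1e-4))
    if compute_se:
        se, cov = _numeric_se(spec, params, y)
    else:
        se, cov = np.full(spec.n_params, np.nan), None
    return ModelFit(
        family=spec.family,
        beta=beta,
        sigma_b=float(sigma),
        dispersion=None if k is None else float(k),
        zi_prob=None if pi is None else float(pi),
        loglik=-float(best.fun),
        n_obs=spec.n_obs,
        n_params=spec.n_params,
        se=se,
        converged=bool(best.success),
        boundary=bool(boundary),
        colnames=spec.colnames,
        message=str(best.message),
        cov=cov,
    )


def wald_linear(fit_result: ModelFit, contrast: np.ndarray):
    """Wald inference for a linear combination c'beta of the fixed effects."""
    if fit_result.cov is None:
        raise ValueError("fit has no covariance matrix (compute_se=False?)")
    c = np.asarray(contrast, dtype=float)
    p = len(fit_result.beta)
    cov_beta = fit_result.cov[:p, :p]
    est = float(c @ fit_result.beta)
    var = float(c @ cov_beta @ c)
    if not np.isfinite(var) or var <= 0:
        raise ValueError("contrast variance is not positive")
    s = np.sqrt(var)
    zcrit = norm.ppf(0.975)
    return est, est - zcrit * s, est + zcrit * s, float(2.0 * norm.sf(abs(est) / s))


def wald(fit_result: ModelFit, coef_index: int):
    """Wald estimate, 95% CI and two-sided normal p-value for one coefficient."""
    est = float(fit_result.beta[coef_index])
    s = float(fit_result.se[coef_index])
    if not np.isfinite(s) or s <= 0:
        raise ValueError(f"no valid standard error for coefficient {coef_index}")
    zcrit = norm.ppf(0.975)
    pval = 2.0 * norm.sf(abs(est) / s)
    return est, est - zcrit * s, est + zcrit * s, float(pval)
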