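"""Second-order confirmatory factor analysis of six cognitive task scores.

The measurement model: three first-order factors — language (picture
vocabulary, reading), mental flexibility (flanker, pattern-comparison
speed), memory recall (picture-sequence memory, auditory verbal learning) —
each with two indicators, underpinned by a single second-order g-factor.
All latent variances are fixed at one, so with first-order loading matrix
``Lambda`` (6x3), second-order loadings ``gamma`` (3,), factor disturbances
``1 - gamma^2`` and task residual variances ``theta`` the implied
covariance of the standardized task scores is

    Sigma = Lambda (gamma gamma' + diag(1 - gamma^2)) Lambda' + diag(theta).

Estimation is plain maximum likelihood (quasi-Newton on a log-variance /
tanh-loading parameterization with fixed starting values, so fits are
deterministic).  Factor scores for g use the regression (Thurstone) method:
w = Sigma^-1 Lambda gamma, applied to task scores standardized with the
statistics stored at fit time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["GFactorModel", "FitReport", "fit_cfa", "factor_scores", "fit_indices"]

N_TASKS = 6
FACTOR_OF_TASK = (0, 0, 1, 1, 2, 2)
MIN_RESIDUAL = 1e-4  # Heywood floor


@dataclass
class GFactorModel:
    first_order_loadings: np.ndarray      # (6,)
    second_order_loadings: np.ndarray     # (3,)
    residual_variances: np.ndarray        # (6,) task residuals
    factor_disturbances: np.ndarray       # (3,) = 1 - gamma^2
    factor_score_weights: np.ndarray      # (6,) standardized tasks -> g
    loglik: float
    discrepancy: float                    # ML fit function value
    n_obs: int
    sample_cov: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    heywood: bool = False

    def implied_covariance(self) -> np.ndarray:
        lam = np.zeros((N_TASKS, 3))
        for t, f in enumerate(FACTOR_OF_TASK):
            lam[t, f] = self.first_order_loadings[t]
        gamma = self.second_order_loadings
        phi = np.outer(gamma, gamma) + np.diag(self.factor_disturbances)
        return lam @ phi @ lam.T + np.diag(self.residual_variances)

    def n_parameters(self) -> int:
        return 15  # 6 loadings + 3 second-order loadings + 6 residuals

    def to_dict(self) -> dict:
        return {
            "first_order_loadings": self.first_order_loadings.tolist(),
            "second_order_loadings": self.second_order_loadings.tolist(),
            "residual_variances": self.residual_variances.tolist(),
            "factor_disturbances": self.factor_disturbances.tolist(),
            "factor_score_weights": self.factor_score_weights.tolist(),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


@dataclass
class FitReport:
    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float] | None
    srmr: float
    omega_l2: float


def _implied(params: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    lam1 = params[:6]
    gamma = np.tanh(params[6:9])
    theta = np.exp(params[9:15])
    lam = np.zeros((N_TASKS, 3))
    for t, f in enumerate(FACTOR_OF_TASK):
        lam[t, f] = lam1[t]
    phi = np.outer(gamma, gamma) + np.diag(1.0 - gamma ** 2)
    return lam @ phi @ lam.T + np.diag(theta), lam1, gamma, theta


def fit_cfa(task_scores: np.ndarray, min_n: int = 100) -> GFactorModel:
    """Maximum-likelihood fit of the second-order g-factor model.

    ``task_scores`` is an (n, 6) array of standardized scores with no
    missing values.  Raises on non-convergence (reporting the gradient
    norm); a Heywood case (residual variance collapsing to zero) is bounded
    at a small positive value with a warning.
    """
    x = np.asarray(task_scores, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_TASKS:
        raise ValueError(f"expected an (n, {N_TASKS}) task-score matrix")
    if np.isnan(x).any():
        raise ValueError("task scores must be complete (no missing values)")
    n = x.shape[0]
    if n < min_n:
        raise ValueError(f"need at least {min_n} observations, got {n}")
    S = np.cov(x, rowvar=False, ddof=1)
    return _fit_to_cov(S, n)


def _fit_to_cov(S: np.ndarray, n: int) -> GFactorModel:
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("sample covariance is singular")

    def discrepancy(params: np.ndarray) -> float:
        sigma, *_ = _implied(params)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10
        return logdet + float(np.trace(np.linalg.solve(sigma, S))) - logdet_s - N_TASKS

    # fixed starting values for determinism
    x0 = np.concatenate([np.full(6, 0.5), np.arctanh(np.full(3, 0.5)),
                         np.log(np.full(6, 0.5))])
    res = optimize.minimize(discrepancy, x0, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    if not res.success and grad_norm > 1e-3:
        raise RuntimeError(
            f"CFA did not converge (max |gradient| = {grad_norm:.3e})")

    sigma, lam1, gamma, theta = _implied(res.x)
    heywood = bool((theta < MIN_RESIDUAL).any())
    if heywood:
        warnings.warn("Heywood case: residual variance bounded at a small positive value")
        theta = np.maximum(theta, MIN_RESIDUAL)

    # sign convention: g loads positively on the first task
    lam = np.zeros((N_TASKS, 3))
    for t, f in enumerate(FACTOR_OF_TASK):
        lam[t, f] = lam1[t]
    for f in range(3):
        idx = [t for t in range(N_TASKS) if FACTOR_OF_TASK[t] == f]
        if lam1[idx[0]] < 0:
            lam1[idx] = -lam1[idx]
            gamma[f] = -gamma[f]
            lam[idx, f] = -lam[idx, f]
    if gamma.sum() < 0:
        gamma = -gamma

    sigma = _implied(np.concatenate([
        lam1, np.arctanh(np.clip(gamma, -1 + 1e-9, 1 - 1e-9)), np.log(theta)]))[0]
    cov_xg = lam @ gamma  # cov(tasks, g), Var(g) = 1
    weights = np.linalg.solve(sigma, cov_xg)
    loglik = -0.5 * n * (N_TASKS * np.log(2 * np.pi)
                         + np.linalg.slogdet(sigma)[1]
                         + float(np.trace(np.linalg.solve(sigma, S))))
    return GFactorModel(
        first_order_loadings=lam1, second_order_loadings=gamma,
        residual_variances=theta, factor_disturbances=1.0 - gamma ** 2,
        factor_score_weights=weights, loglik=loglik,
        discrepancy=float(discrepancy(np.concatenate([
            lam1, np.arctanh(np.clip(gamma, -1 + 1e-9, 1 - 1e-9)), np.log(theta)]))),
        n_obs=n, sample_cov=S, converged=True, heywood=heywood)


def factor_scores(model: GFactorModel, task_scores: np.ndarray) -> np.ndarray:
    """Regression-method g scores for standardized task scores.

    Rows with any missing task value yield NaN (participants with an
    incomplete battery are excluded from analysis).
    """
    x = np.asarray(task_scores, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_TASKS:
        raise ValueError(f"expected an (n, {N_TASKS}) task-score matrix")
    scores = x @ model.factor_score_weights
    scores[np.isnan(x).any(axis=1)] = np.nan
    return scores


def score_validity(model: GFactorModel) -> float:
    """Closed-form correlation between the factor score and true g."""
    w = model.factor_score_weights
    sigma = model.implied_covariance()
    lam = np.zeros((N_TASKS, 3))
    for t, f in enumerate(FACTOR_OF_TASK):
        lam[t, f] = model.first_order_loadings[t]
    cov_xg = lam @ model.second_order_loadings
    return float(w @ cov_xg / np.sqrt(w @ sigma @ w))


def fit_indices(model: GFactorModel, rmsea_ci: bool = True) -> FitReport:
    """Conventional ML fit indices against the independence baseline.

    chi2 = (n - 1) * F_ML; CFI/TLI from the baseline model with all
    covariances zero; RMSEA with a 90% CI from the noncentral chi-square
    (reported as None when the CI is numerically undefined); conventional
    SRMR on the correlation metric; OmegaL2 as the share of total score
    variance attributable to the second-order factor.
    """
    n = model.n_obs
    S = model.sample_cov
    sigma = model.implied_covariance()
    df = N_TASKS * (N_TASKS + 1) // 2 - model.n_parameters()
    chi2 = (n - 1) * model.discrepancy

    # independence baseline: diagonal of S
    d = np.diag(np.diag(S))
    base_f = (np.linalg.slogdet(d)[1]
              + float(np.trace(np.linalg.solve(d, S)))
              - np.linalg.slogdet(S)[1] - N_TASKS)
    chi2_b = (n - 1) * base_f
    df_b = N_TASKS * (N_TASKS - 1) // 2

    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if chi2_b / df_b > 1:
        tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = 1.0
    rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))

    ci = None
    if rmsea_ci:
        ci = _rmsea_ci(chi2, df, n)

    # SRMR over standardized residuals (lower triangle incl. diagonal)
    ds = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(ds, ds)
    tri = resid[np.tril_indices(N_TASKS)]
    srmr = float(np.sqrt(np.mean(tri ** 2)))

    lam = np.zeros((N_TASKS, 3))
    for t, f in enumerate(FACTOR_OF_TASK):
        lam[t, f] = model.first_order_loadings[t]
    general = lam @ model.second_order_loadings
    omega_l2 = float(np.sum(general) ** 2 / np.sum(sigma))

    return FitReport(chi2=chi2, df=df, cfi=cfi, tli=tli, rmsea=float(rmsea),
                     rmsea_ci=ci, srmr=srmr, omega_l2=omega_l2)


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90,
              ) -> tuple[float, float] | None:
    """90% CI by inverting the noncentral chi-square distribution."""
    lo_p, hi_p = (1 + level) / 2, (1 - level) / 2

    def nc_for(p: float) -> float | None:
        f = lambda nc: stats.ncx2.cdf(chi2, df, nc) - p
        if f(0) < 0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2
        if f(hi) > 0:
            return None
        return float(optimize.brentq(f, 0, hi))

    try:
        nc_lo, nc_hi = nc_for(lo_p), nc_for(hi_p)
    except (ValueError, RuntimeError):
        return None
    if nc_lo is None or nc_hi is None:
        return None
    to_rmsea = lambda nc: float(np.sqrt(max(nc, 0.0) / (df * (n - 1))))
    return (to_rmsea(nc_lo), to_rmsea(nc_hi))
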