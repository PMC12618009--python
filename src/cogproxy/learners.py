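"""The three tuned learners: PLS, Elastic Net and Random Forest.

Tuning rules
------------
* PLS: components are added greedily from one upward; a component is kept
  only if it reduces the inner-CV RMSE by at least 0.1% of the total RMSE
  (the RMSE of the intercept-only model, i.e. the standard deviation of the
  target in the training split).
* Elastic Net: the penalty lambda comes from a 20-point log10-spaced grid
  on [1e-10, 10] and the mixture alpha from an 11-point linear grid on
  [0, 1]; the pair with the lowest inner-CV RMSE wins, ties resolved toward
  the larger (more regularizing) lambda.  The loss matches
  sum(y - x b)^2 / (2n) + lambda * ((1 - alpha)/2 * ||b||_2^2 + alpha * ||b||_1).
* Random Forest: 500 trees; (mtry, min_n) candidate pairs drawn by a seeded
  Latin hypercube (3000 by default) over mtry in [1, 90] and min_n in
  [2, 2000]; lowest inner-CV RMSE wins, ties toward the larger min_n.

All tuning uses training-split data only.  Scaled-down grids for compact
studies are available through the config objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

__all__ = ["EnetConfig", "RfConfig", "PlsModel", "pls_fit", "enet_fit", "rf_fit",
           "make_inner_folds"]


def make_inner_folds(n: int, n_folds: int, seed: int,
                     groups: np.ndarray | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded inner-CV folds; with ``groups`` (family ids) whole groups are
    kept within one fold so siblings never straddle an inner split."""
    rng = np.random.default_rng(seed)
    if groups is None:
        kf = KFold(n_splits=n_folds, shuffle=True,
                   random_state=int(rng.integers(2 ** 31 - 1)))
        return list(kf.split(np.arange(n)))
    uniq = np.unique(groups)
    perm = rng.permutation(len(uniq))
    fold_of_group = {g: perm[i] % n_folds for i, g in enumerate(uniq)}
    fold_id = np.array([fold_of_group[g] for g in groups])
    out = []
    for f in range(n_folds):
        test = np.where(fold_id == f)[0]
        train = np.where(fold_id != f)[0]
        if len(test) and len(train):
            out.append((train, test))
    return out


def _cv_rmse(fit_predict, X: np.ndarray, y: np.ndarray,
             folds: list[tuple[np.ndarray, np.ndarray]]) -> float:
    sq = 0.0
    n = 0
    for train, test in folds:
        pred = fit_predict(X[train], y[train], X[test])
        sq += float(np.sum((y[test] - pred) ** 2))
        n += len(test)
    return np.sqrt(sq / n)


# ---------------------------------------------------------------------------
# PLS


@dataclass
class PlsModel:
    n_components: int
    model: PLSRegression
    cv_rmse_path: list[float]
    x_loadings: np.ndarray | None = None
    variance_explained: np.ndarray | None = None  # share of Var(y) per component

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X).ravel()


def pls_fit(X: np.ndarray, y: np.ndarray,
            inner_folds: list[tuple[np.ndarray, np.ndarray]],
            max_components: int | None = None) -> PlsModel:
    """Greedy component selection by the 0.1%-of-total-RMSE rule."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] == 0:
        raise ValueError("no features")
    if np.std(y) == 0:
        raise ValueError("constant target")
    cap = X.shape[1] if max_components is None else min(max_components, X.shape[1])
    total_rmse = float(np.std(y))
    threshold = 1e-3 * total_rmse

    def fp(k):
        def fit_predict(Xtr, ytr, Xte):
            m = PLSRegression(n_components=k, scale=False)
            m.fit(Xtr, ytr)
            return m.predict(Xte).ravel()
        return fit_predict

    path = [_cv_rmse(fp(1), X, y, inner_folds)]
    k = 1
    while k < cap:
        rmse_next = _cv_rmse(fp(k + 1), X, y, inner_folds)
        if rmse_next >= path[-1] - threshold:
            break
        path.append(rmse_next)
        k += 1
    final = PLSRegression(n_components=k, scale=False)
    final.fit(X, y)
    return PlsModel(n_components=k, model=final, cv_rmse_path=path)


def pls_explain(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """Loadings and per-component share of target variance, on the full data.

    Kept separate from the cross-validated predictions: this view is for
    interpreting the components, not for scoring held-out participants.
    """
    m = PLSRegression(n_components=n_components, scale=False)
    y = np.asarray(y, dtype=float).ravel()
    m.fit(X, y)
    scores = m.x_scores_
    var_y = np.var(y)
    explained = np.array([
        np.var(scores[:, [k]] @ m.y_loadings_[:, [k]].T) / var_y
        for k in range(n_components)
    ])
    return PlsModel(n_components=n_components, model=m, cv_rmse_path=[],
                    x_loadings=m.x_loadings_, variance_explained=explained)


# ---------------------------------------------------------------------------
# Elastic Net


@dataclass(frozen=True)
class EnetConfig:
    """Hyperparameter grids for the elastic net."""

    n_lambda: int = 20
    lambda_min: float = 1e-10
    lambda_max: float = 10.0
    n_alpha: int = 11
    alpha_min: float = 0.0
    alpha_max: float = 1.0

    def lambda_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.lambda_min), np.log10(self.lambda_max),
                           self.n_lambda)

    def alpha_grid(self) -> np.ndarray:
        return np.linspace(self.alpha_min, self.alpha_max, self.n_alpha)

    @classmethod
    def scaled_down(cls) -> "EnetConfig":
        return cls(n_lambda=5, n_alpha=3)


@dataclass
class EnetFit:
    coef: np.ndarray
    intercept: float
    lambda_: float
    alpha: float
    cv_rmse: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept


def _enet_model(lam: float, alpha: float) -> ElasticNet:
    # sklearn's objective is 1/(2n)||y - Xb||^2 + a*l1*||b||_1 + a*(1-l1)/2*||b||^2,
    # identical to the stated loss with a = lambda, l1 = alpha.
    return ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                      max_iter=5000, tol=1e-6)


def enet_fit(X: np.ndarray, y: np.ndarray, config: EnetConfig,
             inner_folds: list[tuple[np.ndarray, np.ndarray]]) -> EnetFit:
    """Grid search over (lambda, alpha) by inner-CV RMSE; refit on all rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    lams = config.lambda_grid()
    alphas = config.alpha_grid()
    if len(lams) == 0 or len(alphas) == 0:
        raise ValueError("degenerate hyperparameter grid")
    best = None
    # iterate lambdas descending so ties keep the larger (more regularized) one
    for lam in sorted(lams, reverse=True):
        for alpha in alphas:
            def fit_predict(Xtr, ytr, Xte, lam=lam, alpha=alpha):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = _enet_model(lam, alpha).fit(Xtr, ytr)
                return m.predict(Xte)
            rmse = _cv_rmse(fit_predict, X, y, inner_folds)
            if best is None or rmse < best[0] - 1e-12:
                best = (rmse, lam, alpha)
    rmse, lam, alpha = best
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = _enet_model(lam, alpha).fit(X, y)
    return EnetFit(coef=final.coef_.copy(), intercept=float(final.intercept_),
                   lambda_=lam, alpha=alpha, cv_rmse=rmse)


# ---------------------------------------------------------------------------
# Random Forest


@dataclass(frozen=True)
class RfConfig:
    """Random-forest settings: 500 trees and a Latin-hypercube search over
    (mtry, min_n).  ``tuning_trees`` / ``tuning_subsample`` shrink the
    forests and rows used during the hyperparameter search only; the final
    refit always uses ``n_trees`` on all rows."""

    n_trees: int = 500
    n_candidates: int = 3000
    mtry_range: tuple[int, int] = (1, 90)
    min_n_range: tuple[int, int] = (2, 2000)
    seed: int = 0
    tuning_trees: int | None = None
    tuning_subsample: int | None = None
    tuning_folds: int | None = None

    def candidates(self, n_features: int) -> list[tuple[int, int]]:
        sampler = qmc.LatinHypercube(d=2, seed=self.seed)
        draws = sampler.random(self.n_candidates)
        mtry_hi = min(self.mtry_range[1], n_features)
        mtry = 1 + np.floor(draws[:, 0] * (mtry_hi - self.mtry_range[0] + 1)).astype(int)
        mtry = np.clip(mtry, 1, mtry_hi)
        span = self.min_n_range[1] - self.min_n_range[0] + 1
        min_n = self.min_n_range[0] + np.floor(draws[:, 1] * span).astype(int)
        min_n = np.clip(min_n, self.min_n_range[0], self.min_n_range[1])
        return list(zip(mtry.tolist(), min_n.tolist()))

    @classmethod
    def scaled_down(cls, seed: int = 0) -> "RfConfig":
        return cls(n_candidates=100, seed=seed, tuning_trees=25,
                   tuning_subsample=1000, tuning_folds=3)


@dataclass
class RfFit:
    model: RandomForestRegressor
    mtry: int
    min_n: int
    cv_rmse: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def _rf(n_trees: int, mtry: int, min_n: int, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(n_estimators=n_trees, max_features=mtry,
                                 min_samples_split=min_n, random_state=seed,
                                 n_jobs=1)


def rf_fit(X: np.ndarray, y: np.ndarray, config: RfConfig,
           inner_folds: list[tuple[np.ndarray, np.ndarray]]) -> RfFit:
    """Tune (mtry, min_n) by inner-CV RMSE over Latin-hypercube candidates."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    min_test = min(len(te) for _, te in inner_folds)
    if n < 2 * min_test:
        raise ValueError("too few observations for the inner folds")
    cands = config.candidates(p)
    tune_trees = config.tuning_trees or config.n_trees
    rng = np.random.default_rng(config.seed)
    n_tune_folds = config.tuning_folds or len(inner_folds)
    if config.tuning_subsample and config.tuning_subsample < n:
        sub = np.sort(rng.choice(n, size=config.tuning_subsample, replace=False))
        Xt, yt = X[sub], y[sub]
        folds = make_inner_folds(len(sub), n_tune_folds, config.seed)
    elif n_tune_folds != len(inner_folds):
        Xt, yt = X, y
        folds = make_inner_folds(n, n_tune_folds, config.seed)
    else:
        Xt, yt, folds = X, y, inner_folds
    best = None
    # sort candidates so ties keep the larger min_n (more regularized)
    for mtry, min_n in sorted(set(cands), key=lambda t: (-t[1], t[0])):
        mn = min(min_n, len(Xt))

        def fit_predict(Xtr, ytr, Xte, mtry=mtry, mn=mn):
            m = _rf(tune_trees, mtry, min(mn, len(Xtr)), config.seed).fit(Xtr, ytr)
            return m.predict(Xte)

        rmse = _cv_rmse(fit_predict, Xt, yt, folds)
        if best is None or rmse < best[0] - 1e-12:
            best = (rmse, mtry, min_n)
    rmse, mtry, min_n = best
    final = _rf(config.n_trees, mtry, min(min_n, n), config.seed).fit(X, y)
    return RfFit(model=final, mtry=mtry, min_n=min_n, cv_rmse=rmse)
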