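"""Pre-modelling contracts: exclusion, standardization, harmonization,
imputation and covariate residualization.

All train-fitted transforms are strictly one-directional: statistics are
estimated on the training split only and applied to held-out data, so no
test-set information can leak into a fitted transform.  Follow-up data are
standardized with the corresponding baseline statistics to keep the two
waves on the same scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

__all__ = [
    "StandardizationStats",
    "BlockExclusionReport",
    "detect_outliers_iqr",
    "apply_block_exclusion",
    "combat_harmonize",
    "ComBatModel",
    "impute_environment",
    "residualize",
]


# ---------------------------------------------------------------------------
# standardization


@dataclass
class StandardizationStats:
    """Per-feature mean/sd estimated on one split (train or test).

    Features that are constant in the split (sd = 0) are passed through
    unscaled and flagged, mirroring the all-zero-in-a-site case.
    """

    mean: pd.Series
    sd: pd.Series
    provenance: str = "baseline-train"
    constant: pd.Series = field(default=None)

    @classmethod
    def fit(cls, df: pd.DataFrame, provenance: str = "baseline-train",
            ) -> "StandardizationStats":
        mean = df.mean()
        sd = df.std(ddof=0)
        constant = sd <= 0
        return cls(mean=mean.where(~constant, 0.0), sd=sd.where(~constant, 1.0),
                   provenance=provenance, constant=constant)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df - self.mean) / self.sd


# ---------------------------------------------------------------------------
# outliers and block-level exclusion


def detect_outliers_iqr(values: np.ndarray | pd.Series) -> np.ndarray:
    """Flag values strictly more than 3 interquartile ranges from the
    nearest quartile: x > Q3 + 3*IQR or x < Q1 - 3*IQR.

    Quartiles use linear interpolation (type-7), so the boundary case
    "exactly at Q3 + 3*IQR" is reproducible and not flagged.  NaNs are
    never flagged.  A zero IQR flags every value unequal to the constant,
    with a warning.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 4:
        raise ValueError("need at least 4 non-missing values for quartiles")
    q1, q3 = np.quantile(obs, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("zero IQR: flagging all values unequal to the constant")
        with np.errstate(invalid="ignore"):
            return (x != q1) & ~np.isnan(x)
    with np.errstate(invalid="ignore"):
        return ((x > q3 + 3 * iqr) | (x < q1 - 3 * iqr)) & ~np.isnan(x)


@dataclass
class BlockExclusionReport:
    """Per-participant audit of one feature block's exclusion decision.

    excluded iff QC-flagged, any feature missing, or more than 5% of the
    block's features are 3-IQR outliers.
    """

    table: pd.DataFrame  # columns: qc_flagged, any_missing_feature, n_outlier_features, excluded
    block_name: str
    n_features: int

    @property
    def excluded(self) -> pd.Series:
        return self.table["excluded"]


def apply_block_exclusion(block: pd.DataFrame, qc_flags: pd.Series | None = None,
                          name: str = "block") -> BlockExclusionReport:
    """Block-level exclusion within the current split.

    Outlier masks are computed on the supplied rows only, so train and test
    splits must be passed separately.  Excluded participants keep their
    other blocks; the caller drops only this block's rows.
    """
    n_features = block.shape[1]
    qc = (pd.Series(False, index=block.index) if qc_flags is None
          else qc_flags.reindex(block.index).fillna(False).astype(bool))
    any_missing = block.isna().any(axis=1)
    n_out = pd.Series(0, index=block.index)
    complete = ~any_missing
    if complete.any():
        outl = np.zeros((int(complete.sum()), n_features), dtype=bool)
        sub = block.loc[complete]
        for j, col in enumerate(block.columns):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                outl[:, j] = detect_outliers_iqr(sub[col].values)
        n_out.loc[complete] = outl.sum(axis=1)
    threshold = 0.05 * n_features
    excluded = qc | any_missing | (n_out > threshold)
    table = pd.DataFrame({
        "qc_flagged": qc, "any_missing_feature": any_missing,
        "n_outlier_features": n_out, "excluded": excluded,
    })
    return BlockExclusionReport(table=table, block_name=name, n_features=n_features)


# ---------------------------------------------------------------------------
# ComBat harmonization (parametric empirical Bayes, reference-batch variant)


@dataclass
class ComBatModel:
    """Site location/scale adjustments fitted on a training split.

    Parametric empirical-Bayes shrinkage of per-site feature means and
    variances toward their pooled priors; held-out data are adjusted toward
    the harmonized training reference, so applying the fitted model to the
    training data again is (numerically) a fixed point.
    """

    grand_mean: np.ndarray
    pooled_var: np.ndarray
    gamma_star: dict[str, np.ndarray]   # per-site shrunken location
    delta_star: dict[str, np.ndarray]   # per-site shrunken scale (variance)
    columns: list[str]

    def apply(self, block: pd.DataFrame, site_labels: pd.Series) -> pd.DataFrame:
        x = block[self.columns].to_numpy(dtype=float)
        sites = pd.Series(site_labels, index=block.index).astype(str)
        out = x.copy()
        sd_pool = np.sqrt(self.pooled_var)
        for s in sites.unique():
            rows = (sites == s).values
            gamma = self.gamma_star.get(s)
            delta = self.delta_star.get(s)
            if gamma is None:  # unseen site: pooled parameters
                gamma = np.zeros_like(self.grand_mean)
                delta = np.ones_like(self.pooled_var)
            standardized = (x[rows] - self.grand_mean - gamma * sd_pool) / \
                (sd_pool * np.sqrt(delta))
            out[rows] = standardized * sd_pool + self.grand_mean
        return pd.DataFrame(out, index=block.index, columns=self.columns)


def _fit_combat(block: pd.DataFrame, site_labels: pd.Series,
                empirical_bayes: bool = True) -> ComBatModel:
    x = block.to_numpy(dtype=float)
    sites = pd.Series(site_labels, index=block.index).astype(str)
    uniq = sites.unique()
    if len(uniq) < 2:
        # single batch: identity adjustment
        return ComBatModel(grand_mean=np.zeros(x.shape[1]),
                           pooled_var=np.ones(x.shape[1]),
                           gamma_star={}, delta_star={}, columns=list(block.columns))
    grand_mean = x.mean(axis=0)
    # pooled *within-site* variance: makes fit+apply an exact fixed point
    # for the plain location/scale estimator
    num = np.zeros(x.shape[1])
    den = 0.0
    for s in uniq:
        rows = (sites == s).values
        n_s = int(rows.sum())
        if n_s >= 2:
            num += (n_s - 1) * x[rows].var(axis=0, ddof=1)
            den += n_s - 1
    pooled_var = num / den if den > 0 else x.var(axis=0, ddof=1)
    pooled_var = np.where(pooled_var <= 0, 1.0, pooled_var)
    sd_pool = np.sqrt(pooled_var)
    z = (x - grand_mean) / sd_pool

    gamma_hat, delta_hat, n_per = {}, {}, {}
    for s in uniq:
        rows = (sites == s).values
        n_s = int(rows.sum())
        n_per[s] = n_s
        if n_s < 3:
            warnings.warn(f"site {s!r} has fewer than 3 participants; using pooled parameters")
            gamma_hat[s] = np.zeros(x.shape[1])
            delta_hat[s] = np.ones(x.shape[1])
            continue
        gamma_hat[s] = z[rows].mean(axis=0)
        delta_hat[s] = z[rows].var(axis=0, ddof=1)

    if not empirical_bayes:
        return ComBatModel(grand_mean=grand_mean, pooled_var=pooled_var,
                           gamma_star=gamma_hat, delta_star=delta_hat,
                           columns=list(block.columns))

    # empirical-Bayes priors across sites (parametric: normal / inverse gamma)
    g_all = np.array([gamma_hat[s] for s in uniq])
    d_all = np.array([delta_hat[s] for s in uniq])
    gamma_bar = g_all.mean(axis=0)
    tau2 = g_all.var(axis=0, ddof=1)
    d_mean = d_all.mean(axis=0)
    d_var = d_all.var(axis=0, ddof=1)
    # inverse-gamma moment matching
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(d_var > 0, (2 * d_var + d_mean ** 2) / d_var, np.inf)
        theta = np.where(d_var > 0, (d_mean * d_var + d_mean ** 3) / d_var, d_mean)

    gamma_star, delta_star = {}, {}
    for s in uniq:
        n_s = n_per[s]
        if n_s < 3:
            gamma_star[s] = np.zeros(x.shape[1])
            delta_star[s] = np.ones(x.shape[1])
            continue
        d_star = np.where(np.isfinite(lam),
                          (theta + 0.5 * n_s * delta_hat[s] * (n_s - 1) / n_s)
                          / (0.5 * n_s + lam - 1.0),
                          delta_hat[s])
        d_star = np.where(d_star <= 0, delta_hat[s], d_star)
        with np.errstate(divide="ignore", invalid="ignore"):
            g_star = np.where(tau2 > 0,
                              (n_s * tau2 * gamma_hat[s] + d_star * gamma_bar)
                              / (n_s * tau2 + d_star),
                              gamma_bar)
        gamma_star[s] = g_star
        delta_star[s] = np.maximum(d_star, 1e-8)
    return ComBatModel(grand_mean=grand_mean, pooled_var=pooled_var,
                       gamma_star=gamma_star, delta_star=delta_star,
                       columns=list(block.columns))


def combat_harmonize(train_block: pd.DataFrame, test_block: pd.DataFrame | None,
                     train_sites: pd.Series, test_sites: pd.Series | None = None,
                     empirical_bayes: bool = True,
                     ) -> tuple[pd.DataFrame, pd.DataFrame | None, ComBatModel]:
    """Remove site batch effects; the harmonized training set is the reference.

    Fitted on complete training rows only.  The test split is adjusted with
    its own site means/variances toward the training reference (held-out
    sites unseen at fit time are standardized with their own statistics in
    the training-standardization metric); no test statistic enters the
    training fit.  With ``empirical_bayes=False`` the per-site adjustments
    are removed exactly, which makes fit+apply an exact fixed point; the
    default parametric-EB shrinkage converges to that fixed point rather
    than hitting it in one pass.
    """
    model = _fit_combat(train_block, train_sites, empirical_bayes=empirical_bayes)
    train_h = model.apply(train_block, train_sites)
    test_h = None
    if test_block is not None:
        if test_sites is None:
            raise ValueError("test_sites required when a test block is given")
        test_model = _fit_test_adjustment(model, test_block, test_sites)
        test_h = test_model.apply(test_block, test_sites)
    return train_h, test_h, model


def _fit_test_adjustment(ref: ComBatModel, test_block: pd.DataFrame,
                         test_sites: pd.Series) -> ComBatModel:
    """Location/scale parameters for held-out sites, in the reference metric."""
    x = test_block[ref.columns].to_numpy(dtype=float)
    sites = pd.Series(test_sites, index=test_block.index).astype(str)
    sd_pool = np.sqrt(ref.pooled_var)
    gamma_star, delta_star = {}, {}
    for s in sites.unique():
        rows = (sites == s).values
        n_s = int(rows.sum())
        if n_s < 3:
            warnings.warn(f"test site {s!r} has fewer than 3 participants; "
                          "using pooled parameters")
            gamma_star[s] = np.zeros_like(ref.grand_mean)
            delta_star[s] = np.ones_like(ref.pooled_var)
            continue
        z = (x[rows] - ref.grand_mean) / sd_pool
        gamma_star[s] = z.mean(axis=0)
        var = z.var(axis=0, ddof=1)
        delta_star[s] = np.where(var > 0, var, 1.0)
    return ComBatModel(grand_mean=ref.grand_mean, pooled_var=ref.pooled_var,
                       gamma_star=gamma_star, delta_star=delta_star,
                       columns=ref.columns)


# ---------------------------------------------------------------------------
# environment imputation


def impute_environment(block: pd.DataFrame, categorical: list[str] | None = None,
                       n_neighbors: int = 5) -> pd.DataFrame:
    """Mode-impute categoricals into dummies, standardize, then KNN-impute.

    Applied separately to each split.  Categorical features are imputed by
    their mode (ties broken toward the lowest category label), expanded to
    dummy variables (dropping the first level), standardized, and the
    remaining missing continuous values are imputed by K-nearest neighbours
    (k = 5, Euclidean over mutually observed standardized dimensions).
    Constant features are passed through unscaled.
    """
    categorical = categorical or []
    if block.isna().all().any():
        bad = block.columns[block.isna().all()].tolist()
        raise ValueError(f"feature(s) with all values missing: {bad}")
    parts = []
    cont = block.drop(columns=categorical)
    for col in categorical:
        vals = block[col]
        counts = vals.value_counts()
        mode = sorted(counts[counts == counts.max()].index)[0]
        filled = vals.fillna(mode)
        dummies = pd.get_dummies(filled.astype("category"), prefix=col,
                                 drop_first=True, dtype=float)
        parts.append(dummies)
    cat_df = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=block.index)
    wide = pd.concat([cont, cat_df], axis=1)
    stats = StandardizationStats.fit(wide, provenance="within-split")
    wide_std = stats.transform(wide)
    if wide_std.isna().any().any():
        imputer = KNNImputer(n_neighbors=n_neighbors)
        values = imputer.fit_transform(wide_std)
        wide_std = pd.DataFrame(values, index=wide_std.index, columns=wide_std.columns)
    return wide_std


# ---------------------------------------------------------------------------
# covariate residualization


def residualize(values: pd.Series | np.ndarray, covariates: pd.DataFrame,
                ) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus covariates.

    Collinear covariate columns are dropped (by pivoted QR) with a warning.
    Residuals are orthogonal to every retained covariate column.
    """
    y = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones(len(y)),
                         np.asarray(covariates, dtype=float)])
    if np.isnan(X).any():
        raise ValueError("covariates must be complete")
    q, r, piv = _qr_drop_collinear(X)
    if q.shape[1] < X.shape[1]:
        warnings.warn("collinear covariates dropped before residualization")
    beta = q.T @ y
    return y - q @ beta


def _qr_drop_collinear(X: np.ndarray, tol: float = 1e-10):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * diag[0]).sum())
    return q[:, :rank], r[:rank], piv[:rank]
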