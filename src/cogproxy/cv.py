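"""Nested leave-one-site-out cross-validation across waves and feature sets.

Every data-collection site serves once as the held-out test set; the
remaining sites form the training set, inside which seeded 10-fold
cross-validation (grouped by family) tunes hyperparameters.  Because
families are nested in sites, no family ever straddles a train/test split.
Per fold the engine:

1. standardizes the six task scores (training split with its own
   statistics, test split with its own; follow-up splits reuse the
   corresponding baseline statistics),
2. fits the second-order CFA on the baseline training split only and
   scores every split with the baseline-trained weights,
3. wires the feature-set-specific preprocessing (ComBat for neuroimaging,
   mode/KNN imputation for environment, threshold selection and PC
   residualization for polygenic scores),
4. trains the set's learner and predicts the held-out site, yielding one
   out-of-sample proxy measure per participant.

Predictive performance is summarized per site and pooled (Pearson r,
sum-of-squares R2, MAE, RMSE) with a percentile bootstrap CI for the
pooled correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gfactor
from .learners import EnetConfig, RfConfig, enet_fit, make_inner_folds, pls_fit
from .pgs import PgsPanel, panel_features
from .preprocess import (StandardizationStats, apply_block_exclusion,
                         combat_harmonize, impute_environment)
from .stacking import duplicate_encode, fit_stack
from .synthetic import CohortFrame

__all__ = ["FoldPlan", "StudySettings", "MetricReport", "FeatureSetResult",
           "make_fold_plan", "run_feature_set", "run_fold", "metric_report",
           "bootstrap_ci"]


@dataclass(frozen=True)
class FoldPlan:
    """One fold per site plus the inner-fold seed."""

    test_sites: tuple[str, ...]
    n_inner_folds: int
    seed: int

    def folds(self) -> list[tuple[str, tuple[str, ...]]]:
        return [(t, tuple(s for s in self.test_sites if s != t))
                for t in self.test_sites]


def make_fold_plan(cohort: CohortFrame, n_inner_folds: int = 10,
                   seed: int = 0) -> FoldPlan:
    """Deterministic leave-one-site-out plan over the cohort's sites."""
    base = cohort.wave("baseline")
    sites = sorted(base["site_id"].unique())
    if len(sites) < 3:
        raise ValueError("need at least 3 sites for leave-one-site-out CV")
    counts = base["site_id"].value_counts()
    small = counts[counts < 10]
    if len(small):
        warnings.warn(f"site(s) with fewer than 10 participants kept: "
                      f"{sorted(small.index)}")
    return FoldPlan(test_sites=tuple(sites), n_inner_folds=n_inner_folds, seed=seed)


@dataclass
class StudySettings:
    """Learner and evaluation settings shared across folds."""

    enet: EnetConfig = field(default_factory=EnetConfig)
    rf: RfConfig = field(default_factory=RfConfig)
    n_inner_folds: int = 10
    pls_max_components: int | None = None
    learner_override: str | None = None  # 'identity' mean-of-features baseline
    waves: tuple[str, ...] = ("baseline",)

    @classmethod
    def scaled_down(cls, seed: int = 0, waves: tuple[str, ...] = ("baseline",),
                    ) -> "StudySettings":
        return cls(enet=EnetConfig.scaled_down(), rf=RfConfig.scaled_down(seed),
                   waves=waves)


@dataclass
class MetricReport:
    per_site: pd.DataFrame       # site x (r, r2, mae, rmse, n)
    pooled_r: float
    pooled_r2: float
    pooled_mae: float
    pooled_rmse: float
    mean_r: float
    sd_r: float
    ci_r: tuple[float, float] | None = None


@dataclass
class FeatureSetResult:
    source: str
    proxies: pd.DataFrame        # participant_id, wave, site, family, fold, observed, predicted
    metrics: dict[str, MetricReport]
    fold_artifacts: dict[str, dict]


def _sum_of_squares_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan


def metric_report(observed: pd.Series, predicted: pd.Series, site: pd.Series,
                  n_boot: int = 0, seed: int = 0) -> MetricReport:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ok = ~(np.isnan(obs) | np.isnan(pred))
    obs, pred = obs[ok], pred[ok]
    site = pd.Series(site).values[ok]
    rows = {}
    for s in pd.unique(site):
        m = site == s
        if m.sum() < 3:
            continue
        rows[s] = {
            "r": float(np.corrcoef(obs[m], pred[m])[0, 1]),
            "r2": _sum_of_squares_r2(obs[m], pred[m]),
            "mae": float(np.mean(np.abs(obs[m] - pred[m]))),
            "rmse": float(np.sqrt(np.mean((obs[m] - pred[m]) ** 2))),
            "n": int(m.sum()),
        }
    per_site = pd.DataFrame(rows).T.sort_index()
    ci = bootstrap_ci(obs, pred, n_boot=n_boot, seed=seed) if n_boot else None
    return MetricReport(
        per_site=per_site,
        pooled_r=float(np.corrcoef(obs, pred)[0, 1]) if len(obs) > 2 else np.nan,
        pooled_r2=_sum_of_squares_r2(obs, pred),
        pooled_mae=float(np.mean(np.abs(obs - pred))),
        pooled_rmse=float(np.sqrt(np.mean((obs - pred) ** 2))),
        mean_r=float(per_site["r"].mean()), sd_r=float(per_site["r"].std(ddof=1)),
        ci_r=ci)


def bootstrap_ci(observed: np.ndarray, predicted: np.ndarray, n_boot: int = 1000,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the pooled correlation over participant
    pairs from all test sites combined."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) < 10:
        raise ValueError("need at least 10 pairs for a bootstrap CI")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_boot)
    n = len(obs)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        o, p = obs[idx], pred[idx]
        if np.std(o) == 0 or np.std(p) == 0:
            rs[b] = 1.0 if np.allclose(o * np.std(pred), p * np.std(obs)) else np.nan
            continue
        rs[b] = np.corrcoef(o, p)[0, 1]
    lo, hi = np.nanquantile(rs, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# fold machinery


def _split_scores(cohort: CohortFrame, wave: str, sites: tuple[str, ...] | str,
                  ) -> pd.DataFrame:
    df = cohort.data.xs(wave, level="wave")
    if isinstance(sites, str):
        return df[df["site_id"] == sites]
    return df[df["site_id"].isin(sites)]


def _standardize_g(scores: np.ndarray, stats: tuple[float, float] | None = None,
                   ) -> tuple[np.ndarray, tuple[float, float]]:
    if stats is None:
        ok = ~np.isnan(scores)
        stats = (float(np.mean(scores[ok])), float(np.std(scores[ok])))
    mu, sd = stats
    return (scores - mu) / (sd if sd > 0 else 1.0), stats


class _FoldContext:
    """Targets and bookkeeping for one outer fold (both waves)."""

    def __init__(self, cohort: CohortFrame, test_site: str,
                 train_sites: tuple[str, ...], settings: StudySettings, seed: int):
        self.cohort = cohort
        self.test_site = test_site
        self.train_sites = train_sites
        self.settings = settings
        self.seed = seed
        self.artifacts: dict = {}
        self._prepare_targets()

    def _prepare_targets(self) -> None:
        cohort, settings = self.cohort, self.settings
        tasks = cohort.task_columns
        self.splits: dict[tuple[str, str], pd.DataFrame] = {}
        for wave in set(settings.waves) | {"baseline"}:
            try:
                self.splits[(wave, "train")] = _split_scores(cohort, wave, self.train_sites)
                self.splits[(wave, "test")] = _split_scores(cohort, wave, self.test_site)
            except KeyError:
                continue

        btr = self.splits[("baseline", "train")]
        bte = self.splits[("baseline", "test")]
        self.task_stats = {
            "train": StandardizationStats.fit(btr[tasks], "baseline-train"),
            "test": StandardizationStats.fit(bte[tasks], "baseline-test"),
        }
        btr_std = self.task_stats["train"].transform(btr[tasks]).dropna()
        self.cfa = gfactor.fit_cfa(btr_std.values)
        self.artifacts["task_stats_train"] = self.task_stats["train"].mean.values.copy()
        self.artifacts["cfa_weights"] = self.cfa.factor_score_weights.copy()

        self.g: dict[tuple[str, str], pd.Series] = {}
        self.g_stats: dict[str, tuple[float, float]] = {}
        for (wave, split), df in self.splits.items():
            std = self.task_stats[split].transform(df[tasks])
            raw = gfactor.factor_scores(self.cfa, std.values)
            if wave == "baseline":
                scaled, stats = _standardize_g(raw)
                self.g_stats[split] = stats
            else:
                scaled, _ = _standardize_g(raw, self.g_stats[split])
            self.g[(wave, split)] = pd.Series(scaled, index=df.index)

    def inner_folds(self, index: pd.Index, wave: str) -> list:
        fams = self.splits[(wave, "train")].loc[index, "family_id"].values
        return make_inner_folds(len(index), self.settings.n_inner_folds,
                                self.seed, groups=fams)


def _standardize_pair(train: pd.DataFrame, test: pd.DataFrame,
                      stats_train: StandardizationStats | None = None,
                      stats_test: StandardizationStats | None = None):
    st_tr = stats_train or StandardizationStats.fit(train, "baseline-train")
    st_te = stats_test or StandardizationStats.fit(test, "baseline-test")
    return st_tr.transform(train), st_te.transform(test), st_tr, st_te


def _predict_identity(Xtr, ytr, Xte):
    return np.asarray(Xte, dtype=float).mean(axis=1)


def _fit_mh_env(ctx: _FoldContext, wave: str, source: str) -> dict:
    """PLS route shared by the mental-health and environment sets."""
    cohort, settings = ctx.cohort, ctx.settings
    blocks = cohort.blocks_for(source)
    out = {}
    frames = {}
    for split in ("train", "test"):
        sites = ctx.train_sites if split == "train" else ctx.test_site
        parts = []
        for b in blocks:
            blk = cohort.blocks[b].xs(wave, level="wave")
            df = blk[blk.index.isin(ctx.splits[(wave, split)].index)]
            parts.append(df)
        frames[split] = pd.concat(parts, axis=1)

    if source == "s":
        spec = next(s for s in cohort.truth.block_specs if s.role == "s")
        cat_cols = [c for c in frames["train"].columns
                    if int(c.rsplit("_", 1)[1]) > spec.n_features - spec.n_categorical]
        Xtr = impute_environment(frames["train"], categorical=cat_cols)
        Xte = impute_environment(frames["test"], categorical=cat_cols)
        Xte = Xte.reindex(columns=Xtr.columns, fill_value=0.0)
    else:
        tr = frames["train"].dropna()
        te = frames["test"].dropna()
        if wave == "baseline":
            Xtr, Xte, st_tr, st_te = _standardize_pair(tr, te)
            ctx.artifacts.setdefault("feature_stats", {})[source] = (st_tr, st_te)
        else:
            st_tr, st_te = ctx.artifacts["feature_stats"][source]
            Xtr, Xte = st_tr.transform(tr), st_te.transform(te)

    ytr = ctx.g[(wave, "train")].loc[Xtr.index].dropna()
    Xtr = Xtr.loc[ytr.index]
    folds = ctx.inner_folds(Xtr.index, wave)
    if settings.learner_override == "identity":
        pred = _predict_identity(Xtr.values, ytr.values, Xte.values)
        out["model"] = ("identity",)
    else:
        model = pls_fit(Xtr.values, ytr.values, folds,
                        max_components=settings.pls_max_components)
        pred = model.predict(Xte.values)
        out["model"] = ("pls", model.n_components)
        ctx.artifacts[f"{source}_{wave}_n_components"] = model.n_components
    out["pred"] = pd.Series(pred, index=Xte.index)
    return out


def _fit_pgs(ctx: _FoldContext, wave: str, panel: PgsPanel) -> dict:
    settings = ctx.settings
    g_train = ctx.g[("baseline", "train")].dropna()
    train_ids = ctx.splits[(wave, "train")].index
    test_ids = ctx.splits[(wave, "test")].index
    train_ids = train_ids.intersection(g_train.index)
    Xtr, Xte, chosen = panel_features(panel, g_train, train_ids, test_ids)
    ctx.artifacts[f"pgs_{wave}_thresholds"] = dict(chosen)
    ytr = ctx.g[(wave, "train")].loc[Xtr.index].dropna()
    Xtr = Xtr.loc[ytr.index]
    folds = ctx.inner_folds(Xtr.index, wave)
    if settings.learner_override == "identity":
        pred = _predict_identity(Xtr.values, ytr.values, Xte.values)
    else:
        fit = enet_fit(Xtr.values, ytr.values, settings.enet, folds)
        ctx.artifacts[f"pgs_{wave}_enet"] = (fit.lambda_, fit.alpha)
        pred = fit.predict(Xte.values)
    return {"pred": pd.Series(pred, index=Xte.index), "thresholds": chosen}


def _fit_neuro(ctx: _FoldContext, wave: str) -> dict:
    cohort, settings = ctx.cohort, ctx.settings
    blocks = sorted(cohort.blocks_for("b"))
    train_idx = ctx.splits[(wave, "train")].index
    test_idx = ctx.splits[(wave, "test")].index
    tr_sites = ctx.splits[(wave, "train")]["site_id"]
    te_sites = ctx.splits[(wave, "test")]["site_id"]
    ytr_all = ctx.g[(wave, "train")].dropna()

    train_preds = pd.DataFrame(index=train_idx, columns=blocks, dtype=float)
    test_preds = pd.DataFrame(index=test_idx, columns=blocks, dtype=float)
    enet_params = {}
    for b in blocks:
        blk = cohort.blocks[b].xs(wave, level="wave")
        qc = cohort.qc.xs(wave, level="wave")[b]
        tr = blk[blk.index.isin(train_idx)]
        te = blk[blk.index.isin(test_idx)]
        # split-wise exclusion: QC flag, missingness, 3-IQR outliers over 5%
        rep_tr = apply_block_exclusion(tr, qc, name=b)
        rep_te = apply_block_exclusion(te, qc, name=b)
        tr = tr[~rep_tr.excluded]
        te = te[~rep_te.excluded]
        if len(tr) < 50 or len(te) < 3:
            continue
        tr_std, te_std, *_ = _standardize_pair(tr, te)
        tr_h, te_h, combat = combat_harmonize(tr_std, te_std,
                                              tr_sites.loc[tr.index],
                                              te_sites.loc[te.index])
        ytr = ytr_all.loc[ytr_all.index.intersection(tr_h.index)]
        tr_h = tr_h.loc[ytr.index]
        folds = ctx.inner_folds(tr_h.index, wave)
        if settings.learner_override == "identity":
            train_preds.loc[tr_h.index, b] = _predict_identity(None, None, tr_h.values)
            test_preds.loc[te_h.index, b] = _predict_identity(None, None, te_h.values)
        else:
            fit = enet_fit(tr_h.values, ytr.values, settings.enet, folds)
            enet_params[b] = (fit.lambda_, fit.alpha)
            train_preds.loc[tr_h.index, b] = fit.predict(tr_h.values)
            test_preds.loc[te_h.index, b] = fit.predict(te_h.values)
    ctx.artifacts[f"b_{wave}_enet"] = enet_params

    ytr = ctx.g[(wave, "train")]
    keep_train = train_preds.notna().any(axis=1) & ytr.notna()
    fams = ctx.splits[(wave, "train")].loc[keep_train[keep_train].index, "family_id"].values
    model, _ = fit_stack(train_preds[keep_train], ytr[keep_train], settings.rf,
                         n_inner_folds=settings.n_inner_folds, groups=fams)
    if model.rf is not None:
        ctx.artifacts[f"b_{wave}_rf"] = (model.rf.mtry, model.rf.min_n)
    keep_test = test_preds.notna().any(axis=1)
    encoded_te = duplicate_encode(test_preds[keep_test])
    pred = model.predict(encoded_te)
    return {"pred": pred, "model": model, "encoded_test": encoded_te,
            "set_preds_test": test_preds}


def run_fold(cohort: CohortFrame, source: str, test_site: str,
             train_sites: tuple[str, ...], settings: StudySettings,
             panel: PgsPanel | None = None, seed: int = 0,
             ) -> tuple[pd.DataFrame, dict]:
    """One outer fold for one feature set; returns proxy rows + artifacts."""
    ctx = _FoldContext(cohort, test_site, train_sites, settings, seed)
    rows = []
    for wave in settings.waves:
        if (wave, "test") not in ctx.splits or len(ctx.splits[(wave, "test")]) == 0:
            continue
        if source == "mh" or source == "s":
            res = _fit_mh_env(ctx, wave, source)
        elif source == "b":
            res = _fit_neuro(ctx, wave)
        elif source == "g_pgs":
            if panel is None:
                panel = PgsPanel(cohort.pgs_panel)
            res = _fit_pgs(ctx, wave, panel)
        else:
            raise ValueError(f"unknown feature set {source!r}")
        pred = res["pred"]
        obs = ctx.g[(wave, "test")]
        common = pred.index.intersection(obs.dropna().index)
        df = pd.DataFrame({
            "participant_id": common, "wave": wave, "site_id": test_site,
            "family_id": ctx.splits[(wave, "test")].loc[common, "family_id"].values,
            "observed_g": obs.loc[common].values,
            "predicted_g": pred.loc[common].values,
            "source": source, "fold": test_site,
        })
        rows.append(df)
    proxies = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return proxies, ctx.artifacts


def run_feature_set(cohort: CohortFrame, source: str, plan: FoldPlan,
                    settings: StudySettings | None = None,
                    n_boot: int = 0) -> FeatureSetResult:
    """Leave-one-site-out proxies and metrics for one feature set."""
    settings = settings or StudySettings()
    panel = PgsPanel(cohort.pgs_panel) if source == "g_pgs" else None
    all_rows, artifacts = [], {}
    for test_site, train_sites in plan.folds():
        try:
            rows, art = run_fold(cohort, source, test_site, train_sites,
                                 settings, panel=panel, seed=plan.seed)
        except ValueError as err:
            warnings.warn(f"fold {test_site!r} skipped: {err}")
            artifacts[test_site] = {"skipped": str(err)}
            continue
        all_rows.append(rows)
        artifacts[test_site] = art
    proxies = pd.concat(all_rows, ignore_index=True)
    metrics = {}
    for wave in settings.waves:
        sub = proxies[proxies["wave"] == wave]
        if len(sub):
            metrics[wave] = metric_report(sub["observed_g"], sub["predicted_g"],
                                          sub["site_id"], n_boot=n_boot,
                                          seed=plan.seed)
    return FeatureSetResult(source=source, proxies=proxies, metrics=metrics,
                            fold_artifacts=artifacts)
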