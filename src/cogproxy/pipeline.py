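"""End-to-end default study: proxies for all four feature sets, then the
commonality decomposition of their mixed-model marginal R-squared.

This is the orchestration the package exists for.  With the default
synthetic cohort it produces, per feature set, out-of-sample predicted
cognitive abilities (proxy measures) from leave-one-site-out CV, then:

1. residualizes observed and proxy cognitive abilities on sex, age and
   medication dummies,
2. splits every proxy into centred-within-site and site-average regressors
   (within-family first for the polygenic proxy),
3. fits random-intercept mixed models (family nested in site) for every
   predictor subset and decomposes the full-model marginal R-squared into
   unique and common effects,
4. reports the share of the cognition-mental-health association captured
   by each other proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .commonality import (CenteredRegressors, center_regressors,
                          commonality_partition, commonality_2set,
                          marginal_r2_for_subsets, percent_shared)
from .cv import FoldPlan, StudySettings, make_fold_plan, run_feature_set
from .preprocess import residualize
from .synthetic import (SOURCES, CohortFrame, GenerativeConfig, default_config,
                        generate_cohort, population_commonality, population_r2)

__all__ = ["StudyResult", "run_study", "commonality_from_proxies"]


@dataclass
class StudyResult:
    cohort: CohortFrame
    proxies: pd.DataFrame                  # long: one row per participant x source
    metrics: dict[str, dict]               # source -> wave -> MetricReport
    subset_r2: dict[frozenset, float]
    partition: pd.DataFrame                # 15-term unique/common table
    pairwise: dict[str, dict]              # 2-set analyses vs mental health
    population_partition: pd.DataFrame
    population_subset_r2: dict[frozenset, float]
    fold_artifacts: dict[str, dict] = field(default_factory=dict)


def _residualized_frame(cohort: CohortFrame, proxies: pd.DataFrame,
                        wave: str = "baseline") -> pd.DataFrame:
    """Wide per-participant table of residualized observed g and proxies."""
    base = cohort.wave(wave)
    cov_cols = ["sex"] + cohort.med_columns
    wide = proxies[proxies["wave"] == wave].pivot_table(
        index="participant_id", columns="source", values="predicted_g")
    obs = proxies[proxies["wave"] == wave].groupby("participant_id")["observed_g"].first()
    wide["observed_g"] = obs
    wide["site_id"] = base["site_id"].reindex(wide.index)
    wide["family_id"] = base["family_id"].reindex(wide.index)
    covs = base[cov_cols].reindex(wide.index).astype(float)
    covs["age"] = base["age_months"].reindex(wide.index).astype(float)
    value_cols = [c for c in wide.columns if c not in ("site_id", "family_id")]
    for c in value_cols:
        ok = wide[c].notna()
        res = np.full(len(wide), np.nan)
        res[ok.values] = residualize(wide.loc[ok, c].values, covs.loc[ok])
        wide[c] = res
    return wide


def commonality_from_proxies(cohort: CohortFrame, proxies: pd.DataFrame,
                             sources: tuple[str, ...] = SOURCES,
                             wave: str = "baseline") -> tuple[dict, pd.DataFrame, dict]:
    """All-subset marginal R2, 15-term partition, and 2-set summaries.

    Rows are restricted per analysis to participants with every included
    proxy available.  The polygenic proxy uses the family-then-site
    centring scheme; all others the site scheme.
    """
    wide = _residualized_frame(cohort, proxies, wave=wave)

    def analysis(subset: tuple[str, ...]) -> dict[frozenset, float]:
        cols = list(subset)
        rows = wide[cols + ["observed_g"]].dropna().index
        sub = wide.loc[rows]
        centred = {}
        for s in subset:
            scheme = "family-then-site" if s == "g_pgs" else "site"
            centred[s] = center_regressors(sub[s], sub["site_id"],
                                           family=sub["family_id"], scheme=scheme)
        return marginal_r2_for_subsets(sub["observed_g"], centred,
                                       sub["site_id"], sub["family_id"],
                                       sources=list(subset))

    # four-set analysis on the jointly available participants
    subset_r2 = analysis(tuple(sources))
    partition = commonality_partition(subset_r2, sources)

    # pairwise analyses vs mental health, each on its own availability
    pairwise = {}
    for other in sources:
        if other == "mh":
            continue
        r2 = analysis(("mh", other))
        u_mh, u_other, common = commonality_2set(
            r2[frozenset(("mh", other))], r2[frozenset(("mh",))],
            r2[frozenset((other,))])
        total_mh = r2[frozenset(("mh",))]
        raw, rounded = percent_shared(common, total_mh) if total_mh > 0 else (np.nan, 0)
        pairwise[other] = {
            "r2_mh": total_mh, "r2_other": r2[frozenset((other,))],
            "r2_both": r2[frozenset(("mh", other))],
            "unique_mh": u_mh, "unique_other": u_other, "common": common,
            "percent_shared_raw": raw, "percent_shared": rounded,
        }
    return subset_r2, partition, pairwise


def run_study(config: GenerativeConfig | None = None,
              settings: StudySettings | None = None,
              seed: int = 0, n_boot: int = 0) -> StudyResult:
    """Generate (or accept) a cohort and run the full proxy + commonality
    pipeline for all four feature sets at baseline."""
    config = config or default_config(seed=seed)
    cohort = generate_cohort(config)
    settings = settings or StudySettings.scaled_down(seed)
    plan = make_fold_plan(cohort, n_inner_folds=settings.n_inner_folds, seed=seed)

    all_proxies, metrics, artifacts = [], {}, {}
    for source in SOURCES:
        result = run_feature_set(cohort, source, plan, settings, n_boot=n_boot)
        all_proxies.append(result.proxies)
        metrics[source] = result.metrics
        artifacts[source] = result.fold_artifacts
    proxies = pd.concat(all_proxies, ignore_index=True)

    subset_r2, partition, pairwise = commonality_from_proxies(cohort, proxies)
    pop_partition = population_commonality(cohort.truth)
    pop_r2 = {frozenset(s): population_r2(cohort.truth, s)
              for r in range(1, 5) for s in combinations(SOURCES, r)}
    return StudyResult(cohort=cohort, proxies=proxies, metrics=metrics,
                       subset_r2=subset_r2, partition=partition, pairwise=pairwise,
                       population_partition=pop_partition,
                       population_subset_r2=pop_r2, fold_artifacts=artifacts)
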