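"""Commonality analysis of mixed-model marginal R-squared.

Given out-of-sample proxy measures of cognitive ability (one per feature
source), the analysis fits random-intercept linear mixed models — families
nested within data-collection sites — with each proxy entered as two fixed
effects: its within-site centred values (``cws``) and its site averages
(``savg``).  For the family-correlated polygenic proxy the centring happens
within family first and then within site (``cws,cwf`` / ``savg,favg``).
Marginal R-squared (Nakagawa–Schielzeth) of every predictor subset is then
decomposed by inclusion-exclusion into effects unique to each source and
common to each combination of sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CenteredRegressors",
    "LmmFit",
    "center_regressors",
    "fit_lmm",
    "marginal_r2_for_subsets",
    "commonality_2set",
    "commonality_partition",
    "commonality_4set",
    "percent_shared",
]


# ---------------------------------------------------------------------------
# centring


@dataclass
class CenteredRegressors:
    """Exact split of a proxy into within-cluster and cluster-mean parts."""

    cws: pd.Series       # centred within site (after optional family step)
    savg: pd.Series      # site average (of optional family means)
    scheme: str          # 'site' or 'family-then-site'

    def reconstruct(self) -> pd.Series:
        return self.cws + self.savg


def center_regressors(values: pd.Series, site: pd.Series,
                      family: pd.Series | None = None,
                      scheme: str = "site") -> CenteredRegressors:
    """Split ``values`` into centred-within and averaged parts.

    ``scheme='site'`` returns (value - site mean, site mean).  With
    ``scheme='family-then-site'`` values are first centred/averaged within
    family, and the family means are then centred/averaged within site, so
    cws + savg still reconstructs the input exactly:

        cws  = (x - fam_mean) + (fam_mean - site_mean_of_fam_means)
        savg = site mean of family means
    """
    values = pd.Series(np.asarray(values, dtype=float), index=values.index
                       if isinstance(values, pd.Series) else None)
    site = pd.Series(site, index=values.index)
    if site.isna().any():
        raise ValueError("unknown (missing) site label")
    if scheme == "site":
        savg = values.groupby(site).transform("mean")
        return CenteredRegressors(values - savg, savg, scheme)
    if scheme == "family-then-site":
        if family is None:
            raise ValueError("family labels required for the family-then-site scheme")
        family = pd.Series(family, index=values.index)
        favg = values.groupby(family).transform("mean")
        savg_favg = favg.groupby(site).transform("mean")
        cws_cwf = values - savg_favg
        return CenteredRegressors(cws_cwf, savg_favg, scheme)
    raise ValueError(f"unknown centring scheme {scheme!r}")


# ---------------------------------------------------------------------------
# mixed model


@dataclass
class LmmFit:
    fixed_effects: pd.Series
    tau00: float             # family-in-site random-intercept variance
    sigma2: float            # residual variance
    marginal_r2: float
    conditional_r2: float
    converged: bool
    method: str              # 'reml' or 'ml'

    @property
    def icc(self) -> float:
        denom = self.tau00 + self.sigma2
        return self.tau00 / denom if denom > 0 else 0.0


def fit_lmm(outcome: pd.Series, regressors: pd.DataFrame,
            site: pd.Series, family: pd.Series) -> LmmFit:
    """Random-intercept model: outcome ~ regressors + (1 | site:family).

    Fit by REML; on a singular/non-converged REML fit the model is refit by
    ML with a warning.  tau00 is floored at zero.  Marginal R2 is
    Var(X beta) / (Var(X beta) + tau00 + sigma2); conditional R2 adds tau00
    to the numerator.
    """
    df = pd.DataFrame({"y": np.asarray(outcome, dtype=float)})
    groups = (pd.Series(site).astype(str) + ":" + pd.Series(family).astype(str)).values
    # degenerate (constant) regressors carry no fixed-effect information and
    # would make the design singular; drop them with zero coefficients
    kept = [c for c in regressors.columns
            if np.std(np.asarray(regressors[c], dtype=float)) > 0]
    exog = np.column_stack([np.ones(len(df))] + [np.asarray(regressors[c], dtype=float)
                                                 for c in kept])
    names = ["(Intercept)"] + list(kept)

    def _fit(reml: bool):
        """Multi-optimizer fit keeping the best-likelihood solution.

        The scalar-variance profile is well behaved but individual
        optimizers occasionally stop at poor points without reporting
        failure, so the (restricted) log-likelihoods are compared."""
        best, last_err = None, None
        for opt in ("lbfgs", "bfgs", "cg"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.MixedLM(df["y"].values, exog, groups=groups)
                    res = model.fit(reml=reml, method=opt, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
                continue
            if not np.isfinite(res.llf):
                continue
            if best is None or res.llf > best.llf + 1e-6:
                best = res
            if opt == "bfgs" and best is not None:
                break  # cg is a last resort only
        if best is None:
            raise last_err
        return best

    method = "reml"
    res = _fit(reml=True)
    singular = (not res.converged) or np.asarray(res.cov_re).item() < 1e-10
    if singular:
        warnings.warn("singular REML fit; refitting by ML")
        res = _fit(reml=False)
        method = "ml"

    beta = pd.Series(res.fe_params, index=names)
    tau00 = max(float(np.asarray(res.cov_re).item()), 0.0)
    sigma2 = float(res.scale)
    fixed_part = exog[:, 1:] @ beta.values[1:] if exog.shape[1] > 1 else np.zeros(len(df))
    var_fixed = float(np.var(fixed_part))
    denom = var_fixed + tau00 + sigma2
    return LmmFit(fixed_effects=beta, tau00=tau00, sigma2=sigma2,
                  marginal_r2=var_fixed / denom,
                  conditional_r2=(var_fixed + tau00) / denom,
                  converged=bool(res.converged), method=method)


def marginal_r2_for_subsets(outcome: pd.Series,
                            proxies: Mapping[str, CenteredRegressors],
                            site: pd.Series, family: pd.Series,
                            sources: Sequence[str] | None = None,
                            ) -> dict[frozenset, float]:
    """Marginal R2 of every non-empty predictor subset of ``sources``.

    Each included proxy contributes its (cws, savg) pair as fixed effects.
    All subsets are fitted on the same rows (callers restrict rows to the
    per-analysis availability beforehand).
    """
    if sources is None:
        sources = list(proxies)
    out: dict[frozenset, float] = {}
    for r in range(1, len(sources) + 1):
        for combo in combinations(sources, r):
            cols = {}
            for s in combo:
                cr = proxies[s]
                suffix = ("cws_cwf", "savg_favg") if cr.scheme == "family-then-site" \
                    else ("cws", "savg")
                cols[f"{s}_{suffix[0]}"] = cr.cws
                cols[f"{s}_{suffix[1]}"] = cr.savg
            fit = fit_lmm(outcome, pd.DataFrame(cols), site, family)
            out[frozenset(combo)] = fit.marginal_r2
    return out


# ---------------------------------------------------------------------------
# decomposition


def commonality_2set(r2_ab: float, r2_a: float, r2_b: float,
                     ) -> tuple[float, float, float]:
    """Unique and common effects for two predictor sets.

    unique_a = R2(ab) - R2(b); unique_b = R2(ab) - R2(a);
    common = R2(ab) - unique_a - unique_b.  Negative common effects
    (suppression) are returned as-is.
    """
    unique_a = r2_ab - r2_b
    unique_b = r2_ab - r2_a
    common = r2_ab - unique_a - unique_b
    return unique_a, unique_b, common


def _commonality_coefficient(r2: Mapping[frozenset, float],
                             subset: frozenset, all_sources: frozenset) -> float:
    """C(T) = -sum_{S subseteq T} (-1)^{|S|} R2((V \\ T) u S), with R2({}) = 0.

    The general inclusion-exclusion construction of commonality analysis:
    the coefficient for predictors common to exactly ``subset``.
    """
    rest = all_sources - subset
    members = sorted(subset)
    total = 0.0
    for r in range(len(members) + 1):
        for combo in combinations(members, r):
            s = rest | frozenset(combo)
            val = 0.0 if not s else r2[frozenset(s)]
            total -= (-1) ** r * val
    return total


def commonality_partition(r2: Mapping[frozenset, float],
                          sources: Sequence[str]) -> pd.DataFrame:
    """All 2^k - 1 unique/common coefficients from all-subset R2 values.

    Returns a table with one row per coefficient.  The coefficients sum to
    the full-model R2 exactly (an arithmetic identity of the construction).
    """
    all_sources = frozenset(sources)
    missing = [s for s in map(frozenset, _subsets(sources)) if s not in r2]
    if missing:
        pretty = ", ".join("{" + ",".join(sorted(m)) + "}" for m in missing)
        raise ValueError(f"missing subset R2 value(s): {pretty}")
    rows = []
    for subset in _subsets(sources):
        fs = frozenset(subset)
        coef = _commonality_coefficient(r2, fs, all_sources)
        rows.append({
            "term": "+".join(sorted(subset)),
            "order": len(subset),
            "kind": "unique" if len(subset) == 1 else "common",
            "coefficient": coef,
            "suppression": coef < 0,
        })
    table = pd.DataFrame(rows).sort_values(["order", "term"]).reset_index(drop=True)
    table.attrs["full_r2"] = r2[all_sources]
    return table


def _subsets(sources: Sequence[str]) -> list[tuple[str, ...]]:
    out = []
    for r in range(1, len(sources) + 1):
        out.extend(combinations(sources, r))
    return out


def commonality_4set(all_subset_r2: Mapping[frozenset, float],
                     sources: Sequence[str] = ("mh", "b", "s", "g_pgs"),
                     ) -> pd.DataFrame:
    """Four-set decomposition: 4 unique + 11 common coefficients."""
    if len(sources) != 4:
        raise ValueError("commonality_4set expects exactly four predictor sets")
    return commonality_partition(all_subset_r2, sources)


def percent_shared(common_with_target: float, total_effect: float,
                   ) -> tuple[float, int]:
    """Share (in %) of a total effect that is common with other sources.

    Returns the raw percentage and its nearest-integer rounding, the
    convention used when reporting how much of the cognition-mental-health
    relationship other proxy measures capture.
    """
    if total_effect <= 0:
        raise ValueError("total effect must be positive")
    raw = 100.0 * common_with_target / total_effect
    return raw, int(round(raw))
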