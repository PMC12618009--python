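"""Opportunistic stacking of per-block predictions.

Set-specific learners produce one predicted cognitive-ability value per
feature block; a participant is retained as long as at least one block
prediction exists.  Each prediction column is duplicated, missing entries
are filled with sentinel values (+1000 in the first copy, -1000 in the
second) and a Random Forest learns from the encoded matrix, so the trees
can route around missingness.  Block importance is summarized by mean
absolute Shapley values on held-out data, duplicate pairs combined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .learners import RfConfig, RfFit, make_inner_folds, rf_fit

__all__ = ["EncodedStackMatrix", "StackImportance", "duplicate_encode",
           "fit_stack", "stack_importance", "shapley_values"]

FILL_HI = 1000.0
FILL_LO = -1000.0


@dataclass
class EncodedStackMatrix:
    """2B-column sentinel-encoded prediction matrix (no missing cells)."""

    frame: pd.DataFrame
    block_names: list[str]          # canonical (alphabetical) order
    missing_mask: pd.DataFrame     # original missingness, participant x block
    dropped: pd.Index              # participants excluded (all blocks missing)

    def mask_fills(self) -> pd.DataFrame:
        """Recover the original per-block values (NaN where encoded)."""
        out = {}
        for b in self.block_names:
            col = self.frame[f"{b}__a"].copy()
            col[self.missing_mask[b]] = np.nan
            out[b] = col
        return pd.DataFrame(out)


def duplicate_encode(preds: pd.DataFrame) -> EncodedStackMatrix:
    """Duplicate each block column and sentinel-fill the missing cells.

    Present values are copied identically into both duplicates; missing
    cells become (+1000, -1000).  Participants with every block missing are
    excluded and recorded in ``dropped``.
    """
    blocks = sorted(preds.columns)
    mask = preds[blocks].isna()
    all_missing = mask.all(axis=1)
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} participant(s) with no block "
                      "prediction excluded from stacking")
    kept = preds.loc[~all_missing, blocks]
    mask = mask.loc[~all_missing]
    cols = {}
    for b in blocks:
        cols[f"{b}__a"] = kept[b].fillna(FILL_HI)
        cols[f"{b}__b"] = kept[b].fillna(FILL_LO)
    frame = pd.DataFrame(cols, index=kept.index)
    return EncodedStackMatrix(frame=frame, block_names=blocks, missing_mask=mask,
                              dropped=preds.index[all_missing])


@dataclass
class StackedModel:
    rf: RfFit
    encoder_blocks: list[str]
    single_block: str | None = None  # degenerate pass-through when B = 1

    def predict(self, encoded: EncodedStackMatrix) -> pd.Series:
        if self.single_block is not None:
            vals = encoded.mask_fills()[self.single_block]
            return vals
        return pd.Series(self.rf.predict(encoded.frame.values),
                         index=encoded.frame.index)


def fit_stack(train_preds: pd.DataFrame, y: pd.Series, rf_config: RfConfig,
              n_inner_folds: int = 10,
              groups: np.ndarray | None = None) -> tuple[StackedModel, EncodedStackMatrix]:
    """Random-Forest stacking layer on the encoded training predictions."""
    encoded = duplicate_encode(train_preds)
    y_kept = y.loc[encoded.frame.index]
    if len(encoded.block_names) == 1:
        warnings.warn("single feature block: stacking degenerates to a pass-through")
        return (StackedModel(rf=None, encoder_blocks=encoded.block_names,
                             single_block=encoded.block_names[0]), encoded)
    folds = make_inner_folds(len(y_kept), n_inner_folds, rf_config.seed,
                             groups=groups[~train_preds.isna().all(axis=1).values]
                             if groups is not None else None)
    fit = rf_fit(encoded.frame.values, y_kept.values, rf_config, folds)
    return StackedModel(rf=fit, encoder_blocks=encoded.block_names), encoded


# ---------------------------------------------------------------------------
# Shapley importance


def shapley_values(predict, X: np.ndarray, background: np.ndarray,
                   n_permutations: int = 16, seed: int = 0) -> np.ndarray:
    """Permutation-sampling estimate of interventional Shapley values.

    For each instance, feature values are inserted one at a time into a
    background row along sampled permutations; the telescoping differences
    attribute ``f(x) - f(b)`` exactly across features for every sampled
    (permutation, background-row) pair, so additivity holds for the
    average as well: sum_j phi_ij = f(x_i) - mean_b f(b).
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, m = X.shape
    phi = np.zeros((n, m))
    for _ in range(n_permutations):
        order = rng.permutation(m)
        bg = background[rng.integers(len(background))]
        # rows[k] = background with the first k features (in `order`) replaced
        for i in range(n):
            rows = np.tile(bg, (m + 1, 1))
            for k, j in enumerate(order):
                rows[k + 1:, j] = X[i, j]
            preds = predict(rows)
            diffs = np.diff(preds)
            phi[i, order] += diffs
    return phi / n_permutations


@dataclass
class StackImportance:
    """Mean |SHAP| per original block (duplicates combined), per test site."""

    per_site: pd.DataFrame   # site x block mean |SHAP|
    mean: pd.Series          # across-site mean
    sd: pd.Series            # across-site standard deviation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_abs_shap": self.mean, "sd_across_sites": self.sd})


def stack_importance(model: StackedModel, test_encoded: EncodedStackMatrix,
                     site_labels: pd.Series, background: np.ndarray | None = None,
                     n_background: int = 100, n_permutations: int = 16,
                     max_instances_per_site: int = 60, seed: int = 0,
                     ) -> StackImportance:
    """Per-block Shapley importance on held-out participants.

    |SHAP| values of the two duplicate columns of a block are summed into a
    single per-block magnitude, averaged within each test site, then
    summarized across sites.
    """
    rng = np.random.default_rng(seed)
    X = test_encoded.frame.values
    if background is None:
        idx = rng.choice(len(X), size=min(n_background, len(X)), replace=False)
        background = X[idx]
    sites = pd.Series(site_labels).reindex(test_encoded.frame.index)
    rows_by_site = {}
    for s in sites.dropna().unique():
        pos = np.where((sites == s).values)[0]
        if len(pos) > max_instances_per_site:
            pos = rng.choice(pos, size=max_instances_per_site, replace=False)
        rows_by_site[s] = pos
    predict = (lambda rows: model.rf.predict(rows))
    per_site = {}
    for s, pos in rows_by_site.items():
        phi = shapley_values(predict, X[pos], background,
                             n_permutations=n_permutations,
                             seed=int(rng.integers(2 ** 31 - 1)))
        abs_phi = np.abs(phi)
        combined = {}
        for b in model.encoder_blocks:
            ja = test_encoded.frame.columns.get_loc(f"{b}__a")
            jb = test_encoded.frame.columns.get_loc(f"{b}__b")
            combined[b] = float(abs_phi[:, ja].mean() + abs_phi[:, jb].mean())
        per_site[s] = combined
    table = pd.DataFrame(per_site).T
    return StackImportance(per_site=table, mean=table.mean(axis=0),
                           sd=table.std(axis=0, ddof=1) if len(table) > 1
                           else table.iloc[0] * 0.0)
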