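"""Polygenic-score branch: threshold selection and PC residualization.

Each of the three GWAS definitions contributes candidate scores at ten
p-value thresholds.  Within every training split the threshold whose score
correlates most strongly (in absolute value) with cognitive ability is
selected per definition; the chosen scores are then residualized on four
ancestry principal components, separately within the training and test
splits, before entering the elastic net.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from .preprocess import residualize

__all__ = ["PgsPanel", "select_threshold", "residualize_on_pcs", "panel_features"]

THRESHOLDS = (0.5, 0.1, 0.05, 0.01, 0.001, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)
_COL_RE = re.compile(r"^(pgs\d+)_thr(.+)$")


class PgsPanel:
    """Wide PGS table: one column per (definition, threshold) plus PCs."""

    def __init__(self, table: pd.DataFrame):
        self.table = table
        self.definitions = sorted({m.group(1) for c in table.columns
                                   if (m := _COL_RE.match(c))})
        self.pc_columns = [c for c in table.columns if c.startswith("PC")]

    def thresholds_for(self, definition: str) -> list[float]:
        out = []
        for c in self.table.columns:
            m = _COL_RE.match(c)
            if m and m.group(1) == definition:
                out.append(float(m.group(2)))
        return sorted(out, reverse=True)

    def column(self, definition: str, threshold: float) -> str:
        return f"{definition}_thr{threshold:g}"


def select_threshold(panel: PgsPanel, g: pd.Series,
                     train_ids: pd.Index) -> dict[str, float]:
    """Per-definition threshold with the strongest |r| against g, on the
    training split only.  Ties go to the larger (more inclusive) threshold;
    all-constant score columns are excluded with a warning."""
    sub = panel.table.loc[panel.table.index.intersection(train_ids)]
    g_train = g.loc[sub.index]
    chosen: dict[str, float] = {}
    for d in panel.definitions:
        best: tuple[float, float] | None = None
        for t in panel.thresholds_for(d):  # descending: ties keep larger threshold
            col = sub[panel.column(d, t)]
            if col.std(ddof=0) == 0:
                warnings.warn(f"constant PGS column {panel.column(d, t)!r} skipped")
                continue
            r = abs(float(np.corrcoef(col.values, g_train.values)[0, 1]))
            if best is None or r > best[0] + 1e-15:
                best = (r, t)
        if best is None:
            raise ValueError(f"no usable threshold for definition {d!r}")
        chosen[d] = best[1]
    return chosen


def residualize_on_pcs(scores: pd.DataFrame, pcs: pd.DataFrame) -> pd.DataFrame:
    """Regress each score on the ancestry PCs within the given split and
    return the residuals (used as learner features)."""
    pcs = pcs.loc[scores.index]
    out = {}
    for col in scores.columns:
        out[col] = residualize(scores[col].values, pcs)
    return pd.DataFrame(out, index=scores.index)


def panel_features(panel: PgsPanel, g_train: pd.Series,
                   train_ids: pd.Index, test_ids: pd.Index,
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Full branch: threshold selection on train, split-wise PC residuals."""
    chosen = select_threshold(panel, g_train, train_ids)
    cols = [panel.column(d, t) for d, t in chosen.items()]
    train = panel.table.loc[panel.table.index.intersection(train_ids), cols]
    test = panel.table.loc[panel.table.index.intersection(test_ids), cols]
    pcs = panel.table[panel.pc_columns]
    train_r = residualize_on_pcs(train, pcs)
    test_r = residualize_on_pcs(test, pcs)
    return train_r, test_r, chosen
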