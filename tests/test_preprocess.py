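"""Exclusion, harmonization, imputation and residualization contracts."""

import numpy as np
import pandas as pd
import pytest

from cogproxy.preprocess import (StandardizationStats, apply_block_exclusion,
                                 combat_harmonize, detect_outliers_iqr,
                                 impute_environment, residualize)


class TestIqrOutliers:
    def test_boundary_value_not_flagged(self):
        """'over 3 IQR' is strict: a value exactly at Q3 + 3*IQR stays.

        With 102 points the interpolated quartiles depend only on inner
        order statistics, so the probe can sit exactly on the fence."""
        inner = np.linspace(-1.0, 1.0, 101)
        arr = np.append(inner, 1e6)  # placeholder max
        q1, q3 = np.quantile(arr, [0.25, 0.75])
        fence = q3 + 3 * (q3 - q1)
        arr[-1] = fence
        assert np.allclose(np.quantile(arr, [0.25, 0.75]), [q1, q3])
        assert not detect_outliers_iqr(arr)[-1]
        arr[-1] = fence + 1e-9
        assert detect_outliers_iqr(arr)[-1]

    def test_single_extreme_point(self, rng):
        x = rng.normal(size=200)
        x[17] = x.std() * 50
        mask = detect_outliers_iqr(x)
        assert mask[17] and mask.sum() == 1

    def test_quantile_oracle_1_to_99_plus_extreme(self):
        """Brute-force type-7 quantile recomputation on [1..99, 10000]."""
        x = np.array(list(range(1, 100)) + [10000.0])
        sx = np.sort(x)
        pos_q1, pos_q3 = 0.25 * 99, 0.75 * 99  # (n-1)*p indexing
        brute = lambda pos: sx[int(pos)] + (pos - int(pos)) * \
            (sx[int(pos) + 1] - sx[int(pos)])
        q1, q3 = brute(pos_q1), brute(pos_q3)
        want = (x > q3 + 3 * (q3 - q1)) | (x < q1 - 3 * (q3 - q1))
        got = detect_outliers_iqr(x)
        assert np.array_equal(got, want)
        assert set(x[got]) == {10000.0}

    def test_zero_iqr_flags_unequal_values(self):
        x = np.array([5.0] * 20 + [6.0])
        with pytest.warns(UserWarning, match="zero IQR"):
            mask = detect_outliers_iqr(x)
        assert mask[-1] and mask.sum() == 1

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            detect_outliers_iqr(np.array([1.0, 2.0, np.nan, np.nan]))


class TestBlockExclusion:
    @pytest.fixture()
    def block167(self, rng):
        return pd.DataFrame(rng.normal(size=(400, 167)),
                            columns=[f"f{j}" for j in range(167)])

    def _spike(self, block, row, n_cols):
        block = block.copy()
        block.iloc[row, :n_cols] = 1e4
        return block

    def test_nine_outlier_features_excluded(self, block167):
        spiked = self._spike(block167, 0, 9)  # 9 > 0.05 * 167 = 8.35
        rep = apply_block_exclusion(spiked)
        assert rep.excluded.iloc[0]
        assert rep.table.loc[rep.table.index[0], "n_outlier_features"] == 9

    def test_eight_outlier_features_retained(self, block167):
        spiked = self._spike(block167, 0, 8)
        rep = apply_block_exclusion(spiked)
        assert not rep.excluded.iloc[0]

    def test_qc_flag_alone_excludes(self, block167):
        qc = pd.Series(False, index=block167.index)
        qc.iloc[3] = True
        rep = apply_block_exclusion(block167, qc)
        assert rep.excluded.iloc[3]
        assert rep.table["n_outlier_features"].iloc[3] == 0

    def test_missing_feature_excludes(self, block167):
        block167.iloc[5, 10] = np.nan
        rep = apply_block_exclusion(block167)
        assert rep.excluded.iloc[5]

    def test_report_invariant(self, block167):
        spiked = self._spike(block167, 2, 20)
        spiked.iloc[4, 0] = np.nan
        qc = pd.Series(False, index=spiked.index)
        qc.iloc[6] = True
        rep = apply_block_exclusion(spiked, qc)
        t = rep.table
        want = t.qc_flagged | t.any_missing_feature | \
            (t.n_outlier_features > 0.05 * rep.n_features)
        assert (t.excluded == want).all()


class TestComBat:
    def test_single_site_identity(self, rng):
        block = pd.DataFrame(rng.normal(size=(100, 5)))
        sites = pd.Series(["a"] * 100)
        out, _, _ = combat_harmonize(block, None, sites)
        assert np.allclose(out.values, block.values)

    def test_additive_shift_removed(self, rng):
        n = 2000
        base = rng.normal(size=(2 * n, 4))
        delta = 1.5
        base[n:] += delta
        block = pd.DataFrame(base)
        sites = pd.Series(["a"] * n + ["b"] * n)
        out, _, _ = combat_harmonize(block, None, sites)
        gap = out.iloc[:n].mean() - out.iloc[n:].mean()
        assert np.all(np.abs(gap) < 0.05 * delta)

    def test_idempotent_fixed_point(self, rng):
        """fit+apply is an exact fixed point without shrinkage, and the EB
        variant converges toward it."""
        n = 500
        base = rng.normal(size=(2 * n, 3))
        base[n:] *= 1.4
        base[n:] += 0.8
        block = pd.DataFrame(base)
        sites = pd.Series(["a"] * n + ["b"] * n)
        once, _, _ = combat_harmonize(block, None, sites, empirical_bayes=False)
        twice, _, _ = combat_harmonize(once, None, sites, empirical_bayes=False)
        rms = np.sqrt(np.mean((twice.values - once.values) ** 2))
        assert rms < 1e-6
        once_eb, _, _ = combat_harmonize(block, None, sites)
        twice_eb, _, _ = combat_harmonize(once_eb, None, sites)
        rms_eb = np.sqrt(np.mean((twice_eb.values - once_eb.values) ** 2))
        assert rms_eb < 0.02

    def test_test_split_pulled_to_reference(self, rng):
        n = 1000
        tr = pd.DataFrame(rng.normal(size=(2 * n, 3)))
        tr_sites = pd.Series(["a"] * n + ["b"] * n)
        te = pd.DataFrame(rng.normal(size=(n, 3)) + 2.0)
        te_sites = pd.Series(["c"] * n)
        tr_h, te_h, _ = combat_harmonize(tr, te, tr_sites, te_sites)
        assert np.all(np.abs(te_h.mean() - tr_h.mean()) < 0.1)

    def test_no_test_information_in_train_fit(self, rng):
        n = 300
        tr = pd.DataFrame(rng.normal(size=(2 * n, 3)))
        tr_sites = pd.Series(["a"] * n + ["b"] * n)
        te = pd.DataFrame(rng.normal(size=(50, 3)))
        te_sites = pd.Series(["c"] * 50)
        _, _, m1 = combat_harmonize(tr, te, tr_sites, te_sites)
        _, _, m2 = combat_harmonize(tr, te * 100 + 7, tr_sites, te_sites)
        for s in m1.gamma_star:
            assert np.array_equal(m1.gamma_star[s], m2.gamma_star[s])
            assert np.array_equal(m1.delta_star[s], m2.delta_star[s])


class TestImputeEnvironment:
    def test_complete_block_just_standardized(self, rng):
        block = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        out = impute_environment(block)
        want = (block - block.mean()) / block.std(ddof=0)
        assert np.allclose(out.values, want.values)

    def test_knn_unanimous_neighbours(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 2))
        block = pd.DataFrame(np.column_stack([base, np.zeros(30)]),
                             columns=list("abc"))
        # five exact neighbours in (a, b) share c = v; the missing row matches
        block.loc[:4, ["a", "b"]] = [[5.0, 5.0]] * 5
        block.loc[:4, "c"] = 2.0
        block.loc[5, ["a", "b"]] = [5.0, 5.0]
        block.loc[5, "c"] = np.nan
        out = impute_environment(block)
        # v was imputed: row 5's value equals the neighbours' shared value
        assert out.loc[5, "c"] == pytest.approx(out.loc[0, "c"])

    def test_beats_mean_imputation_on_correlated_data(self, rng):
        n = 600
        u = rng.normal(size=n)
        x = np.column_stack([u + 0.3 * rng.normal(size=n) for _ in range(4)])
        mask = rng.random((n, 4)) < 0.10
        x_missing = x.copy()
        x_missing[mask] = np.nan
        block = pd.DataFrame(x_missing, columns=list("abcd"))
        out = impute_environment(block)
        x_std = (x - np.nanmean(x_missing, 0)) / np.nanstd(x_missing, 0)
        knn_rmse = np.sqrt(np.mean((out.values[mask] - x_std[mask]) ** 2))
        mean_rmse = np.sqrt(np.mean(x_std[mask] ** 2))  # mean-impute = 0 after scaling
        assert knn_rmse < mean_rmse

    def test_all_missing_feature_rejected(self):
        block = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="all values missing"):
            impute_environment(block)

    def test_categorical_mode_ties_lowest_label(self):
        block = pd.DataFrame({
            "cat": [0.0, 0.0, 1.0, 1.0, np.nan, 2.0],
            "x": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
        })
        out = impute_environment(block, categorical=["cat"])
        # tie between 0 and 1 -> imputed 0 -> row 4 has no dummy set
        dummy_cols = [c for c in out.columns if c.startswith("cat_")]
        raw = out[dummy_cols].iloc[4]
        assert (raw == out[dummy_cols].min()).all()


class TestResidualize:
    def test_orthogonal_values_unchanged_up_to_mean(self, rng):
        n = 500
        cov = pd.DataFrame({"age": rng.normal(size=n)})
        y = rng.normal(size=n)
        y -= np.polyval(np.polyfit(cov["age"], y, 1), cov["age"])  # orthogonalize
        res = residualize(y, cov)
        assert np.allclose(res, y - y.mean(), atol=1e-10)

    def test_covariate_column_zeroed(self, rng):
        cov = pd.DataFrame({"age": rng.normal(size=100)})
        res = residualize(2.0 * cov["age"].values + 1.0, cov)
        assert np.max(np.abs(res)) < 1e-10

    def test_variance_recovery(self, rng):
        n = 10_000
        age = rng.normal(size=n)
        e = rng.normal(scale=0.7, size=n)
        res = residualize(2.0 * age + e, pd.DataFrame({"age": age}))
        assert np.var(res) == pytest.approx(np.var(e), rel=0.02)
        assert abs(res @ age) < 1e-8 * n

    def test_collinear_covariates_dropped(self, rng):
        n = 50
        a = rng.normal(size=n)
        cov = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.warns(UserWarning, match="collinear"):
            res = residualize(a + rng.normal(size=n), cov)
        assert abs(res @ a) < 1e-8 * n


class TestStandardization:
    def test_constant_feature_passed_through_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [4.0, 4.0, 4.0]})
        stats = StandardizationStats.fit(df)
        out = stats.transform(df)
        assert stats.constant["c"] and not stats.constant["x"]
        assert np.allclose(out["c"], 4.0)

    def test_followup_uses_stored_baseline_stats(self, rng):
        base = pd.DataFrame(rng.normal(loc=5, scale=2, size=(200, 2)),
                            columns=list("xy"))
        fup = pd.DataFrame(rng.normal(loc=6, scale=2, size=(100, 2)),
                           columns=list("xy"))
        stats = StandardizationStats.fit(base)
        once = stats.transform(fup)
        # idempotence: transforming an already-transformed frame with the
        # *same stored stats* is not applied twice in the pipeline; the
        # stats object itself is immutable under transform
        again = stats.transform(fup)
        pd.testing.assert_frame_equal(once, again)
        assert once["x"].mean() != pytest.approx(0.0, abs=1e-3)
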