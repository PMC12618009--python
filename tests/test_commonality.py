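"""Centring schemes, mixed-model marginal R-squared, and the unique/common
decomposition with its brute-force oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cogproxy.commonality import (center_regressors, commonality_2set,
                                  commonality_4set, commonality_partition,
                                  fit_lmm, marginal_r2_for_subsets,
                                  percent_shared)

SOURCES4 = ("mh", "b", "s", "g_pgs")


class TestCentering:
    def test_site_scheme_arithmetic(self):
        vals = pd.Series([1.0, 3.0, 2.0, 6.0])
        site = pd.Series(["A", "A", "B", "B"])
        cr = center_regressors(vals, site)
        assert list(cr.cws) == [-1.0, 1.0, -2.0, 2.0]
        assert list(cr.savg) == [2.0, 2.0, 4.0, 4.0]

    def test_constant_proxy_centres_to_zero(self):
        vals = pd.Series([5.0] * 6)
        site = pd.Series(["A"] * 3 + ["B"] * 3)
        cr = center_regressors(vals, site)
        assert (cr.cws == 0).all()

    def test_reconstruction_exact_to_one_ulp(self, rng):
        """cws + savg must reproduce the input exactly up to the single
        rounding of the subtract-then-add round trip (<= 1 ulp)."""
        vals = pd.Series(rng.normal(size=200))
        site = pd.Series(rng.choice(["A", "B", "C"], size=200))
        fam = pd.Series(rng.integers(0, 60, size=200))
        for scheme in ("site", "family-then-site"):
            cr = center_regressors(vals, site, family=fam, scheme=scheme)
            np.testing.assert_allclose(cr.reconstruct().values, vals.values,
                                       rtol=0, atol=1e-14)

    def test_family_then_site_hand_example(self):
        """Two single-child families per site: the site average becomes the
        mean of family means (= values), worked by hand on 6 rows."""
        vals = pd.Series([1.0, 3.0, 2.0, 4.0, 6.0, 8.0])
        site = pd.Series(["A", "A", "B", "B", "C", "C"])
        fam = pd.Series(["f1", "f2", "f3", "f4", "f5", "f6"])
        cr = center_regressors(vals, site, family=fam, scheme="family-then-site")
        # family means equal the values themselves; site averages: 2, 3, 7
        assert list(cr.savg) == [2.0, 2.0, 3.0, 3.0, 7.0, 7.0]
        assert list(cr.cws) == [-1.0, 1.0, -1.0, 1.0, -1.0, 1.0]

    def test_sibling_pair_example(self):
        """With a two-child family, cws,cwf departs from plain site centring."""
        vals = pd.Series([1.0, 5.0, 2.0])      # one sibling pair + singleton
        site = pd.Series(["A", "A", "A"])
        fam = pd.Series(["f1", "f1", "f2"])
        cr = center_regressors(vals, site, family=fam, scheme="family-then-site")
        # family means: 3, 3, 2 -> site mean of family means per row uses
        # row-level transform: mean(3,3,2) = 8/3
        assert np.allclose(cr.savg, 8.0 / 3.0)
        assert np.allclose(cr.cws, vals - 8.0 / 3.0)

    def test_unknown_site_label_rejected(self):
        vals = pd.Series([1.0, 2.0])
        site = pd.Series(["A", None])
        with pytest.raises(ValueError, match="site"):
            center_regressors(vals, site)


def simulate_lmm(rng, n_sites=21, fams_per_site=300, kids=(1, 2),
                 var_fixed=0.3, tau00=0.2, sigma2=0.5):
    """Direct draw from the random-intercept model (the recovery oracle)."""
    rows = []
    x_all, y_all = [], []
    for s in range(n_sites):
        for f in range(fams_per_site):
            fam_id = f"s{s}f{f}"
            u = rng.normal(scale=np.sqrt(tau00))
            for _ in range(rng.choice(kids)):
                x = rng.normal()
                y = np.sqrt(var_fixed) * x + u + rng.normal(scale=np.sqrt(sigma2))
                rows.append((f"site{s}", fam_id))
                x_all.append(x)
                y_all.append(y)
    site = pd.Series([r[0] for r in rows])
    fam = pd.Series([r[1] for r in rows])
    return (pd.Series(y_all), pd.DataFrame({"x": x_all}), site, fam)


class TestFitLmm:
    def test_zero_fixed_effects_zero_marginal_r2(self, rng):
        y, x, site, fam = simulate_lmm(rng, fams_per_site=40, var_fixed=0.0)
        fit = fit_lmm(y, x * 0.0, site, fam)
        assert fit.marginal_r2 == pytest.approx(0.0, abs=1e-6)

    def test_variance_component_recovery(self):
        """(Var(Xb), tau00, sigma2) = (0.3, 0.2, 0.5) recovered within
        +-0.02 on marginal and conditional R2 at 21 sites x 300 families."""
        rng = np.random.default_rng(77)
        y, x, site, fam = simulate_lmm(rng)
        fit = fit_lmm(y, x, site, fam)
        assert fit.marginal_r2 == pytest.approx(0.30, abs=0.02)
        assert fit.conditional_r2 == pytest.approx(0.50, abs=0.02)
        assert fit.tau00 == pytest.approx(0.20, abs=0.02)
        assert fit.sigma2 == pytest.approx(0.50, abs=0.02)
        assert fit.icc == pytest.approx(0.2 / 0.7, abs=0.03)

    def test_no_clustering_marginal_equals_conditional(self, rng):
        y, x, site, fam = simulate_lmm(rng, fams_per_site=60, tau00=0.0)
        fit = fit_lmm(y, x, site, fam)
        assert abs(fit.conditional_r2 - fit.marginal_r2) < 0.02


class TestTwoSetDecomposition:
    def test_printed_marginal_r2_values(self):
        """Worked from the three baseline mixed models for the mental-health
        x neuroimaging pair: R2 = (0.272, 0.098, 0.238)."""
        u_mh, u_b, common = commonality_2set(0.272, 0.098, 0.238)
        assert u_mh == pytest.approx(0.034, abs=1e-12)
        assert u_b == pytest.approx(0.174, abs=1e-12)
        assert common == pytest.approx(0.064, abs=1e-12)

    def test_second_set_adds_nothing(self):
        assert commonality_2set(0.2, 0.2, 0.0) == pytest.approx((0.2, 0.0, 0.0))

    def test_full_redundancy(self):
        assert commonality_2set(0.2, 0.2, 0.2) == pytest.approx((0.0, 0.0, 0.2))

    def test_terms_sum_to_joint_r2(self, rng):
        for _ in range(20):
            r2a, r2b = rng.uniform(0, 0.5, size=2)
            r2ab = max(r2a, r2b) + rng.uniform(0, 0.2)
            parts = commonality_2set(r2ab, r2a, r2b)
            assert sum(parts) == pytest.approx(r2ab, abs=1e-12)


def random_consistent_r2_map(rng, sources=SOURCES4):
    """All-subset R2 values from a random joint-Gaussian predictor
    structure: guaranteed internally consistent (monotone, submodular-free
    but valid)."""
    k = len(sources)
    a = rng.uniform(-0.6, 0.6, size=k)          # cov(predictor_i, y)
    m = rng.uniform(-0.4, 0.4, size=(k, k))
    cov = m @ m.T + np.eye(k)                    # predictor covariance
    scale = np.sqrt(np.diag(cov))
    cov = cov / np.outer(scale, scale)
    a = a * 0.9                                  # keep total R2 < 1
    out = {}
    for r in range(1, k + 1):
        for combo_idx in combinations(range(k), r):
            idx = list(combo_idx)
            sub = cov[np.ix_(idx, idx)]
            r2 = float(a[idx] @ np.linalg.solve(sub, a[idx]))
            out[frozenset(sources[i] for i in idx)] = r2
    return out


def brute_force_partition(r2_map, sources=SOURCES4):
    """Independent oracle: solve the defining linear system
    R2(S) = sum_{T : T n S != 0} C(T) for all 15 subsets."""
    subsets = [frozenset(c) for r in range(1, 5)
               for c in combinations(sources, r)]
    A = np.array([[1.0 if t & s else 0.0 for t in subsets] for s in subsets])
    b = np.array([r2_map[s] for s in subsets])
    coef = np.linalg.solve(A, b)
    return dict(zip(subsets, coef))


class TestFourSetDecomposition:
    def test_additive_orthogonal_sources(self):
        v = dict(zip(SOURCES4, (0.1, 0.2, 0.05, 0.15)))
        r2 = {frozenset(c): sum(v[s] for s in c)
              for r in range(1, 5) for c in combinations(SOURCES4, r)}
        table = commonality_4set(r2, SOURCES4)
        for _, row in table.iterrows():
            parts = row["term"].split("+")
            if row["kind"] == "unique":
                assert row["coefficient"] == pytest.approx(v[parts[0]], abs=1e-12)
            else:
                assert row["coefficient"] == pytest.approx(0.0, abs=1e-12)

    def test_total_redundancy(self):
        r2 = {frozenset(c): 0.3
              for r in range(1, 5) for c in combinations(SOURCES4, r)}
        table = commonality_4set(r2, SOURCES4)
        quad = table[table["order"] == 4]["coefficient"].iloc[0]
        rest = table[table["order"] < 4]["coefficient"]
        assert quad == pytest.approx(0.3, abs=1e-12)
        assert np.allclose(rest, 0.0, atol=1e-12)

    def test_matches_brute_force_oracle_on_random_maps(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            r2 = random_consistent_r2_map(rng)
            table = commonality_4set(r2, SOURCES4)
            want = brute_force_partition(r2)
            got = {frozenset(t.split("+")): c
                   for t, c in zip(table["term"], table["coefficient"])}
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-12)

    def test_missing_subset_named_in_error(self):
        r2 = {frozenset(c): 0.1
              for r in range(1, 5) for c in combinations(SOURCES4, r)}
        del r2[frozenset(("mh", "b"))]
        with pytest.raises(ValueError, match="b,mh"):
            commonality_4set(r2, SOURCES4)

    def test_conservation_on_fitted_models(self, rng):
        """Unique + common terms reproduce the full-model marginal R2 to
        1e-10 when the subset R2s come from actual mixed-model fits."""
        y, x, site, fam = simulate_lmm(rng, fams_per_site=30)
        proxies = {}
        for i, s in enumerate(SOURCES4):
            noise = rng.normal(size=len(y))
            vals = pd.Series(0.5 * y.values + noise, index=y.index)
            scheme = "family-then-site" if s == "g_pgs" else "site"
            proxies[s] = center_regressors(vals, site, family=fam, scheme=scheme)
        r2 = marginal_r2_for_subsets(y, proxies, site, fam, sources=SOURCES4)
        table = commonality_partition(r2, SOURCES4)
        assert table["coefficient"].sum() == pytest.approx(
            r2[frozenset(SOURCES4)], abs=1e-10)


class TestPercentShared:
    @pytest.mark.parametrize("common,total,expected", [
        (6.48, 9.8, 66), (1.93, 9.21, 21), (6.12, 9.75, 63), (7.05, 8.97, 79)])
    def test_reported_sharing_percentages(self, common, total, expected):
        raw, rounded = percent_shared(common, total)
        assert rounded == expected

    def test_zero_common_zero_percent(self):
        raw, rounded = percent_shared(0.0, 0.5)
        assert raw == 0.0 and rounded == 0

    def test_non_positive_total_rejected(self):
        with pytest.raises(ValueError):
            percent_shared(0.1, 0.0)
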