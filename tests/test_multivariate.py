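import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import f_oneway

import reeftrend as rt
from reeftrend.multivariate import (
    ResemblanceMatrix, _dummies, _gower, bray_curtis, mean_dissimilarities,
    pairwise_year_tests, permanova, transform_log1p,
)

from conftest import make_matrix


def _euclid_res(x, groups):
    d = np.abs(x[:, None] - x[None, :])
    d = d / max(d.max(), 1e-9) * 99.0  # scale-invariant statistic; keep in [0,100]
    meta = pd.DataFrame({"year_bin": np.asarray(groups).astype(str)},
                        index=[f"s{i}" for i in range(len(x))])
    return ResemblanceMatrix(values=d, ids=list(meta.index), meta=meta)


def _oneway(res, groups, **kw):
    tab = permanova(res, terms=[("Group", _dummies(groups))],
                    denominators={"Group": "Residual"}, **kw)
    return tab.loc[tab["Source"] == "Group"].iloc[0]


class TestTransform:
    def test_log1p_values(self):
        m = make_matrix([[0.0, math.e - 1.0]], ["a", "b"])
        out = transform_log1p(m)
        assert out.densities.iloc[0, 0] == 0.0
        assert out.densities.iloc[0, 1] == pytest.approx(1.0)

    def test_negative_rejected(self):
        m = make_matrix([[1.0]], ["a"])
        m.densities.iloc[0, 0] = -0.5
        with pytest.raises(ValueError, match="negative"):
            transform_log1p(m)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, x1, x2):
        if x1 < x2:
            assert math.log1p(x1) < math.log1p(x2)


class TestBrayCurtis:
    def test_hand_computed_value_with_dummy(self):
        m = make_matrix([[2.0, 0.0], [0.0, 2.0]], ["a", "b"])
        res = bray_curtis(m, dummy_density=1.0)
        assert res.values[0, 1] == pytest.approx(100 * 4 / 6)

    def test_two_empty_samples_are_identical_with_dummy(self):
        m = make_matrix([[0.0, 0.0], [0.0, 0.0]], ["a", "b"])
        res = bray_curtis(m)
        assert res.values[0, 1] == 0.0

    def test_identical_samples_zero(self):
        m = make_matrix([[1.0, 2.0], [1.0, 2.0]], ["a", "b"])
        assert bray_curtis(m).values[0, 1] == 0.0

    def test_empty_sample_without_dummy_rejected(self):
        m = make_matrix([[0.0, 0.0], [1.0, 0.0]], ["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(m, dummy_density=None)

    def test_dummy_never_increases_dissimilarity_and_bounds_it(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(1.0, 2.0, size=(12, 6)) * (rng.random((12, 6)) < 0.6)
        x[:, 0] += 0.5  # every pair shares taxon 0
        m = make_matrix(x, [f"t{j}" for j in range(6)])
        with_d = bray_curtis(m).values
        without = bray_curtis(m, dummy_density=None).values
        iu = np.triu_indices(12, 1)
        assert (with_d[iu] <= without[iu] + 1e-12).all()
        assert (with_d[iu] < 100).all()

    def test_csv_round_trip(self, tmp_path):
        m = make_matrix([[2.0, 0.0], [0.0, 2.0], [1.0, 1.0]], ["a", "b"])
        res = bray_curtis(m)
        res.to_csv(tmp_path / "r.csv")
        back = ResemblanceMatrix.from_csv(tmp_path / "r.csv", m.meta)
        np.testing.assert_allclose(back.values, res.values, atol=1e-9)


class TestPermanova:
    @pytest.mark.parametrize("trial", range(4))
    def test_oneway_pseudo_f_equals_classical_anova_f(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(9, 30))
        k = int(rng.integers(2, 4))
        g = rng.integers(0, k, n)
        while len(np.unique(g)) < k:
            g = rng.integers(0, k, n)
        x = rng.normal(size=n)
        row = _oneway(_euclid_res(x, g), g, n_perm=99, seed=0)
        f_ref = f_oneway(*[x[g == j] for j in range(k)]).statistic
        assert row["pseudo-F"] == pytest.approx(f_ref, abs=1e-10)

    def test_exhaustive_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=6)
        g = np.array([0, 0, 0, 1, 1, 1])
        row = _oneway(_euclid_res(x, g), g, n_perm=99, seed=0)
        assert row["n_perm_used"] == 720
        f_obs = f_oneway(x[g == 0], x[g == 1]).statistic
        count = sum(
            f_oneway(x[list(p)][g == 0], x[list(p)][g == 1]).statistic >= f_obs - 1e-12
            for p in itertools.permutations(range(6)))
        assert row["p"] == pytest.approx(count / 720, abs=1e-12)

    def test_exhaustive_p_invariant_to_sample_order(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=6)
        g = np.array([0, 0, 1, 1, 2, 2])
        row = _oneway(_euclid_res(x, g), g, n_perm=99, seed=0)
        order = rng.permutation(6)
        row2 = _oneway(_euclid_res(x[order], g[order]), g[order], n_perm=99, seed=3)
        assert row2["pseudo-F"] == pytest.approx(row["pseudo-F"], rel=1e-10)
        assert row2["p"] == pytest.approx(row["p"], abs=1e-12)

    def test_matches_scikit_bio_oneway_on_bray_curtis(self, disturbed_community):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        m = disturbed_community.matrix
        res = bray_curtis(transform_log1p(m))
        g = m.meta["year_bin"].to_numpy()
        row = _oneway(res, g, n_perm=99, seed=0)
        dm = skbio_dist.DistanceMatrix(res.values, ids=res.ids)
        ref = skbio_dist.permanova(dm, grouping=g, permutations=99)
        assert row["pseudo-F"] == pytest.approx(ref["test statistic"], rel=1e-8)

    def test_partition_and_huygens_total(self, disturbed_community):
        m = disturbed_community.matrix
        res = bray_curtis(transform_log1p(m))
        tab = permanova(res, n_perm=99, seed=0)
        total = tab.loc[tab.Source == "Total"].iloc[0]
        n = res.n
        iu = np.triu_indices(n, 1)
        assert total["SS"] == pytest.approx((res.values[iu] ** 2).sum() / n, rel=1e-9)
        terms = tab[~tab.Source.isin(["Total"])]
        assert terms["SS"].sum() == pytest.approx(total["SS"], rel=1e-9)
        assert terms["df"].sum() == n - 1

    def test_too_few_permutations_rejected(self, disturbed_community):
        res = bray_curtis(disturbed_community.matrix)
        with pytest.raises(ValueError, match="n_perm"):
            permanova(res, n_perm=50)

    def test_detects_strong_year_effect(self):
        # the affected year must span several month blocks for the
        # block-permutation test to resolve it
        design = rt.generate_design(
            n_sites=8, years=[2009, 2011],
            months_by_year={2009: [3, 5, 7, 9, 11], 2011: [3, 5, 7, 9, 11]},
            seed=3)
        params = rt.guild_scenario_params()[:5]
        patch = rt.disturbance_scenario(
            {p.guild: 0.95 for p in params}, "2011", occupancy_share=0.5)
        com = rt.generate_community(design, patch.apply(params), seed=13)
        res = bray_curtis(transform_log1p(com.matrix))
        tab = permanova(res, n_perm=199, seed=1)
        assert tab.loc[tab.Source == "Year", "p"].iloc[0] <= 0.05


class TestPairwise:
    def test_duplicated_bins_are_exchangeable(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(1, 1, size=(5, 4))
        dens = np.vstack([x, x])
        meta = [{"site": f"S{i % 3}", "year": 2011 + j, "month": 7,
                 "year_bin": str(2011 + j), "depth_m": 30.0, "longitude": -86.0,
                 "area_m2": 200.0} for j in range(2) for i in range(5)]
        m = make_matrix(dens, [f"t{j}" for j in range(4)], meta_rows=meta)
        res = bray_curtis(m)
        pairs, square = pairwise_year_tests(res, n_perm=199, seed=0)
        row = pairs.iloc[0]
        assert row["p"] > 0.5
        assert square.loc["2011", "2012"] == pytest.approx(
            (square.loc["2011", "2011"] + square.loc["2012", "2012"]) / 2, rel=0.2)

    def test_disjoint_communities_near_100(self):
        dens = [[1000.0, 0.0]] * 3 + [[0.0, 1000.0]] * 3
        meta = [{"site": f"S{i}", "year": 2011 + (i >= 3), "month": 7,
                 "year_bin": str(2011 + (i >= 3)), "depth_m": 30.0,
                 "longitude": -86.0, "area_m2": 200.0} for i in range(6)]
        m = make_matrix(dens, ["a", "b"], meta_rows=meta)
        pairs, square = pairwise_year_tests(bray_curtis(m), n_perm=199, seed=0)
        assert square.loc["2011", "2012"] > 99.0

    def test_mean_dissimilarities_match_direct_average(self, disturbed_community):
        res = bray_curtis(transform_log1p(disturbed_community.matrix))
        labels = res.meta["year_bin"]
        square = mean_dissimilarities(res, labels)
        ii = np.flatnonzero((labels == rt.PRE_BIN).to_numpy())
        jj = np.flatnonzero((labels == "2010").to_numpy())
        assert square.loc[rt.PRE_BIN, "2010"] == pytest.approx(
            res.values[np.ix_(ii, jj)].mean())
        block = res.values[np.ix_(ii, ii)]
        assert square.loc[rt.PRE_BIN, rt.PRE_BIN] == pytest.approx(
            block[np.triu_indices(len(ii), 1)].mean())
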