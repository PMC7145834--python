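import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import reeftrend as rt
from reeftrend.delta_index import (
    DeltaIndexSeries, SubmodelFit, filter_taxa, fit_binomial, fit_lognormal,
    monte_carlo_index, percent_change, submodel_contrasts,
)

from conftest import make_matrix


def _meta(n_pre, n_post, n_sites=4, post_bin="2011", rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    depths = rng.uniform(20, 60, n_sites)
    lons = rng.uniform(-88, -85, n_sites)
    for i in range(n_pre + n_post):
        s = i % n_sites
        rows.append({"site": f"S{s}", "year": 2009 if i < n_pre else 2011,
                     "month": 7, "year_bin": rt.PRE_BIN if i < n_pre else post_bin,
                     "depth_m": depths[s], "longitude": lons[s], "area_m2": 200.0})
    return pd.DataFrame(rows, index=[f"x{i}" for i in range(len(rows))])


class TestFilterTaxa:
    def test_occurrence_fraction_above_threshold_kept(self):
        meta = _meta(26, 224)
        dens = np.zeros((250, 2))
        dens[:3, 0] = 1.0            # 3/26 pre = 11.5% -> kept
        dens[0, 1] = 1.0             # 1/26 pre
        dens[26:31, 1] = 1.0         # 5/224 post -> both <= 5% -> dropped
        m = make_matrix(dens, ["common", "rare"], meta_rows=meta.to_dict("records"))
        m.densities.index = meta.index
        m.meta.index = meta.index
        assert filter_taxa(m) == ["common"]

    def test_zero_threshold_keeps_all_observed(self):
        meta = _meta(4, 4)
        dens = np.zeros((8, 2))
        dens[0, 0] = 1.0
        m = make_matrix(dens, ["seen", "never"], meta_rows=meta.to_dict("records"))
        assert filter_taxa(m, fo_threshold=0.0) == ["seen"]


class TestBinomialFit:
    def test_all_present_rejected(self):
        meta = _meta(8, 8)
        y = pd.Series(1, index=meta.index)
        with pytest.raises(ValueError, match="both outcomes"):
            fit_binomial(y, meta)

    def test_all_absent_bin_flagged_inestimable(self):
        meta = _meta(12, 12)
        rng = np.random.default_rng(0)
        y = pd.Series(np.r_[rng.permutation([1] * 6 + [0] * 6), np.zeros(12)],
                      index=meta.index).astype(int)
        fit = fit_binomial(y, meta, covariates=False)
        assert "2011" in fit.flags["inestimable"]
        assert fit.estimable == [rt.PRE_BIN]

    def test_constant_occupancy_recovered_with_nominal_coverage(self):
        # p = 0.7, 16 sites x 15 surveys, site SD 0.5: the lsmean CI should
        # cover logit(0.7) at close to the nominal rate, and slope CIs 0
        target = logit(0.7)
        cover = 0
        slope_cover = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            meta = _meta(120, 120, n_sites=16, rng=rng)
            u = dict(zip([f"S{s}" for s in range(16)], rng.normal(0, 0.5, 16)))
            eta = target + meta["site"].map(u).to_numpy()
            y = pd.Series((rng.random(len(meta)) < expit(eta)).astype(int),
                          index=meta.index)
            fit = fit_binomial(y, meta, covariates=True)
            mu, se = fit.lsmeans[rt.PRE_BIN], fit.se[rt.PRE_BIN]
            cover += (mu - 1.96 * se) <= target <= (mu + 1.96 * se)
            slope_cover += abs(fit.site_sd - 0.5) < 0.5
        assert cover / n_rep >= 0.86
        assert slope_cover / n_rep >= 0.8

    def test_matches_lme4_glmer(self, tmp_path, disturbed_community):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        m = disturbed_community.matrix
        dens = m.densities["guild:herbivore"]
        z = rt.zscored_covariates(m.meta)
        df = pd.DataFrame({
            "y": (dens > 0).astype(int),
            "bin": m.meta["year_bin"].astype(str),
            "site": m.meta["site"],
            "depth_z": z["depth_z"], "lon_z": z["lon_z"],
        })
        df.to_csv(tmp_path / "d.csv", index=False)
        script = textwrap.dedent("""
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(TRUE)[1])
            d$bin <- relevel(factor(d$bin), ref = "pre-DWH")
            f <- glmer(y ~ bin + depth_z + lon_z + (1|site), data = d,
                       family = binomial, nAGQ = 25)
            nd <- data.frame(bin = levels(d$bin), depth_z = 0, lon_z = 0)
            eta <- predict(f, newdata = nd, re.form = NA, type = "link")
            out <- data.frame(bin = levels(d$bin), eta = eta,
                              site_sd = sqrt(unlist(VarCorr(f))[1]))
            write.csv(out, commandArgs(TRUE)[2], row.names = FALSE)
        """)
        (tmp_path / "fit.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "fit.R"), str(tmp_path / "d.csv"),
                        str(tmp_path / "out.csv")], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv").set_index("bin")
        fit = fit_binomial((dens > 0).astype(int), m.meta, covariates=True)
        for b in fit.estimable:
            assert fit.lsmeans[b] == pytest.approx(ref.loc[b, "eta"], abs=2e-2)
        assert fit.site_sd == pytest.approx(ref["site_sd"].iloc[0], abs=5e-2)


class TestLognormalFit:
    def test_constant_density_recovers_log_constant(self):
        meta = _meta(8, 8)
        y = pd.Series(2.0, index=meta.index)
        fit = fit_lognormal(y, meta, covariates=False)
        for b in fit.estimable:
            assert fit.lsmeans[b] == pytest.approx(np.log(2.0), abs=1e-6)
        assert fit.site_sd < 1e-3

    def test_zero_densities_rejected(self):
        meta = _meta(4, 4)
        y = pd.Series([1.0, 0.0] * 4, index=meta.index)
        with pytest.raises(ValueError, match="positive"):
            fit_lognormal(y, meta)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(9)
        meta = _meta(150, 150, n_sites=10, rng=rng)
        mu = np.log(0.05)
        y = pd.Series(np.exp(rng.normal(mu, 0.6, len(meta))), index=meta.index)
        fit = fit_lognormal(y, meta, covariates=False)
        se = fit.se[rt.PRE_BIN]
        assert abs(fit.lsmeans[rt.PRE_BIN] - mu) < 3 * se

    def test_thin_bin_flagged_but_estimable(self):
        meta = _meta(10, 1)
        y = pd.Series(np.exp(np.random.default_rng(2).normal(0, 0.3, 11)),
                      index=meta.index)
        fit = fit_lognormal(y, meta, covariates=False)
        assert "2011" in fit.flags["thin"]
        assert "2011" in fit.estimable
        assert fit.se["2011"] > 0

    def test_balanced_lsmeans_equal_raw_bin_means(self):
        rng = np.random.default_rng(3)
        meta = _meta(12, 12)
        y = pd.Series(np.exp(rng.normal(0.5, 0.4, 24)), index=meta.index)
        fit = fit_lognormal(y, meta, covariates=False)
        raw = np.log(y).groupby(meta["year_bin"]).mean()
        for b in fit.estimable:
            assert fit.lsmeans[b] == pytest.approx(raw[b], abs=1e-6)

    def test_se_shrinks_like_one_over_sqrt_n(self):
        rng = np.random.default_rng(4)
        ses = []
        for n in (40, 160):
            meta = _meta(n, n, n_sites=8, rng=np.random.default_rng(4))
            y = pd.Series(np.exp(rng.normal(0, 0.5, 2 * n)), index=meta.index)
            fit = fit_lognormal(y, meta, covariates=False)
            ses.append(fit.se[rt.PRE_BIN])
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.3)


def _manual_fit(kind, bins, mu, se, df=np.inf):
    se_s = pd.Series(se, index=bins, dtype=float)
    cov = pd.DataFrame(np.diag(se_s ** 2), index=bins, columns=bins)
    return SubmodelFit(kind=kind, bins=list(bins), estimable=list(bins),
                       lsmeans=pd.Series(mu, index=bins, dtype=float), se=se_s,
                       cov=cov, df_resid=df, site_sd=0.0, converged=True)


class TestMonteCarloIndex:
    def test_degenerate_variance_gives_point_mass(self):
        bins = [rt.PRE_BIN, "2010"]
        b = _manual_fit("binomial", bins, [0.5, -0.3], [0.0, 0.0])
        l = _manual_fit("lognormal", bins, [1.2, 0.4], [0.0, 0.0])
        s = monte_carlo_index(b, l, n_draws=2000, seed=0)
        for bin_ in bins:
            row = s.table.loc[bin_]
            assert row["ci_hi"] - row["ci_lo"] == pytest.approx(0.0, abs=1e-12)
            assert row["index"] == pytest.approx(
                expit(b.lsmeans[bin_]) * np.exp(l.lsmeans[bin_]))

    def test_zero_logit_mean_gives_half_presence_factor(self):
        bins = [rt.PRE_BIN]
        b = _manual_fit("binomial", bins, [0.0], [0.0])
        l = _manual_fit("lognormal", bins, [0.0], [0.0])
        s = monte_carlo_index(b, l, n_draws=2000, seed=0)
        assert s.table["index"].iloc[0] == pytest.approx(0.5)

    def test_perfectly_correlated_submodels_match_quantile_transform(self):
        # with r = 1 and equal SEs the draw product is a monotone function of
        # one normal deviate; CI must match the closed-form quantile transform
        bins = [rt.PRE_BIN, "2010", "2011"]
        mp = np.array([0.0, 0.5, 1.0])
        ml = 2.0 * mp - 1.0                    # exactly linear -> r = 1
        sig = 0.3
        b = _manual_fit("binomial", bins, mp, [sig] * 3)
        l = _manual_fit("lognormal", bins, ml, [sig] * 3)
        s = monte_carlo_index(b, l, n_draws=100_000, seed=1)
        assert s.adjustment_applied
        assert s.r == pytest.approx(1.0)
        from scipy.stats import norm
        for i, bin_ in enumerate(bins):
            z = norm.ppf([0.025, 0.975])
            closed = expit(mp[i] + sig * z) * np.exp(ml[i] + sig * z)
            assert s.table.loc[bin_, "ci_lo"] == pytest.approx(closed[0], rel=0.02)
            assert s.table.loc[bin_, "ci_hi"] == pytest.approx(closed[1], rel=0.02)

    def test_missing_bin_in_either_submodel_missing_in_index(self):
        b = _manual_fit("binomial", [rt.PRE_BIN, "2010"], [0.1, 0.2], [0.1, 0.1])
        l = _manual_fit("lognormal", [rt.PRE_BIN], [1.0], [0.1])
        s = monte_carlo_index(b, l, n_draws=2000, seed=0)
        assert list(s.table.index) == [rt.PRE_BIN]

    def test_seed_reproducibility(self):
        bins = [rt.PRE_BIN, "2010"]
        b = _manual_fit("binomial", bins, [0.5, -0.5], [0.2, 0.2])
        l = _manual_fit("lognormal", bins, [1.0, 0.0], [0.3, 0.3])
        s1 = monte_carlo_index(b, l, n_draws=5000, seed=7, taxon="t")
        s2 = monte_carlo_index(b, l, n_draws=5000, seed=7, taxon="t")
        pd.testing.assert_frame_equal(s1.table, s2.table)


class TestPercentChange:
    def test_sixty_two_percent_decline(self):
        s = DeltaIndexSeries(
            taxon="t", table=pd.DataFrame(
                {"index": [0.10, 0.038]}, index=[rt.PRE_BIN, "2010"]),
            r=np.nan, r_p=np.nan, adjustment_applied=False, n_draws=0)
        assert percent_change(s, rt.PRE_BIN, "2010") == pytest.approx(-62.0)

    def test_equal_and_doubling(self):
        s = DeltaIndexSeries(
            taxon="t", table=pd.DataFrame({"index": [0.2, 0.2, 0.4]},
                                          index=["a", "b", "c"]),
            r=np.nan, r_p=np.nan, adjustment_applied=False, n_draws=0)
        assert percent_change(s, "a", "b") == 0.0
        assert percent_change(s, "a", "c") == pytest.approx(100.0)

    def test_missing_bin_rejected(self):
        s = DeltaIndexSeries(
            taxon="t", table=pd.DataFrame({"index": [0.2]}, index=["a"]),
            r=np.nan, r_p=np.nan, adjustment_applied=False, n_draws=0)
        with pytest.raises(ValueError, match="no index estimate"):
            percent_change(s, "a", "b")


class TestSubmodelContrasts:
    def test_reference_is_pre_bin_when_present(self):
        bins = [rt.PRE_BIN] + [str(y) for y in range(2010, 2018)]
        fit = _manual_fit("binomial", bins, np.zeros(9), np.full(9, 0.2))
        out = submodel_contrasts(fit, seed=0)
        assert len(out) == 8                       # eight post-bin comparisons
        assert (out["reference"] == rt.PRE_BIN).all()

    def test_post_only_taxon_uses_first_estimable_bin(self):
        bins = ["2011", "2012", "2013"]            # invader pattern
        fit = _manual_fit("lognormal", bins, [0.0, 0.5, 1.0], [0.2] * 3, df=30)
        out = submodel_contrasts(fit, seed=0)
        assert (out["reference"] == "2011").all()
        assert list(out.index) == ["2012", "2013"]

    def test_single_estimable_bin_yields_no_contrasts(self):
        fit = _manual_fit("binomial", ["2011"], [0.0], [0.2])
        assert submodel_contrasts(fit, seed=0).empty


class TestInvariances:
    def test_site_relabelling_leaves_index_unchanged(self, disturbed_community):
        m = disturbed_community.matrix
        dens = m.densities["guild:herbivore"]
        fit = lambda meta: monte_carlo_index(
            fit_binomial((dens > 0).astype(int), meta),
            fit_lognormal(dens[dens > 0], meta), n_draws=2000, seed=3, taxon="h")
        base = fit(m.meta)
        relabel = m.meta.copy()
        relabel["site"] = relabel["site"].map(lambda s: f"Z-{s}")
        again = fit(relabel)
        np.testing.assert_allclose(again.table["index"], base.table["index"],
                                   rtol=1e-6)

    def test_density_rescaling_scales_index_linearly(self, disturbed_community):
        m = disturbed_community.matrix
        dens = m.densities["guild:herbivore"]
        c = 7.0

        def index_of(d):
            return monte_carlo_index(
                fit_binomial((d > 0).astype(int), m.meta),
                fit_lognormal(d[d > 0], m.meta), n_draws=2000, seed=3,
                taxon="h").table["index"]

        np.testing.assert_allclose(index_of(dens * c), index_of(dens) * c,
                                   rtol=1e-5)
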