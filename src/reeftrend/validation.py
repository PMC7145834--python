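"""Simulation-based validation experiments for the analysis pipeline.

Each function here re-derives a quantitative property of the methods from
scratch — oracle equivalence of the distance-based pseudo-F, permutation and
familywise calibration under null simulations, recovery of encoded guild
declines at the study's design scale, Monte Carlo CI coverage, and
closed-form identities.  They are used by the test suite and by the
repository's acceptance script; sizes are arguments so both can choose their
own compute budget.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from . import synthetic
from .survey_io import PRE_BIN
from .multivariate import (
    ResemblanceMatrix, _dummies, bray_curtis, permanova, transform_log1p,
)
from .diversity import dunnett_pvalues, indices
from .delta_index import fit_binomial, fit_lognormal, monte_carlo_index, percent_change

logger = logging.getLogger("reeftrend")

#: Stock guild-decline magnitudes exercised by the recovery experiment.
RECOVERY_DECLINES = {
    "herbivore": 0.96,
    "small demersal browser": 0.87,
    "small demersal invertivore": 0.82,
    "generalist carnivore": 0.64,
    "piscivore": 0.73,
}


def _euclid_res(x: np.ndarray, groups) -> ResemblanceMatrix:
    d = np.abs(x[:, None] - x[None, :])
    d = d / max(d.max(), 1e-9) * 99.0
    meta = pd.DataFrame({"year_bin": np.asarray(groups).astype(str)},
                        index=[f"s{i}" for i in range(len(x))])
    return ResemblanceMatrix(values=d, ids=list(meta.index), meta=meta)


def _oneway_row(res, groups, **kw):
    tab = permanova(res, terms=[("Group", _dummies(groups))],
                    denominators={"Group": "Residual"}, **kw)
    return tab.loc[tab["Source"] == "Group"].iloc[0]


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

def anova_equivalence(seed: int = 0, n_instances: int = 5) -> dict:
    """Pseudo-F vs classical one-way ANOVA F on univariate Euclidean data,
    and exhaustive-enumeration agreement of the permutation p at n = 6."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    max_f_err = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(9, 30))
        k = int(rng.integers(2, 4))
        g = rng.integers(0, k, n)
        while len(np.unique(g)) < k:
            g = rng.integers(0, k, n)
        x = rng.normal(size=n)
        row = _oneway_row(_euclid_res(x, g), g, n_perm=99, seed=0)
        f_ref = f_oneway(*[x[g == j] for j in range(k)]).statistic
        max_f_err = max(max_f_err, abs(float(row["pseudo-F"]) - f_ref))

    x = rng.normal(size=6)
    g = np.array([0, 0, 0, 1, 1, 1])
    row = _oneway_row(_euclid_res(x, g), g, n_perm=99, seed=0)
    f_obs = f_oneway(x[g == 0], x[g == 1]).statistic
    count = sum(
        f_oneway(x[list(p)][g == 0], x[list(p)][g == 1]).statistic >= f_obs - 1e-12
        for p in itertools.permutations(range(6)))
    return {"max_F_error": float(max_f_err),
            "exact_p_error": abs(float(row["p"]) - count / 720)}


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def permanova_null_calibration(n_rep: int = 500, n_perm: int = 199,
                               alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the year term under a no-year-effect simulation."""
    months = {y: [3, 5, 7, 9] for y in (2009, 2011, 2013)}
    params = synthetic.guild_scenario_params()[:5]
    rej = 0
    for rep in range(n_rep):
        design = synthetic.generate_design(
            n_sites=6, years=list(months), months_by_year=months,
            seed=100_000 + seed * 7919 + rep)
        com = synthetic.generate_community(design, params,
                                           seed=200_000 + seed * 7919 + rep)
        res = bray_curtis(transform_log1p(com.matrix))
        tab = permanova(res, n_perm=n_perm, seed=seed + rep)
        rej += float(tab.loc[tab.Source == "Year", "p"].iloc[0]) <= alpha
    return rej / n_rep


def dunnett_fwer(n_rep: int = 1000, k: int = 8, m: int = 10,
                 alpha: float = 0.05, seed: int = 0) -> float:
    """Familywise error rate of the Dunnett adjustment under a global null
    (one-way layout, k many-to-one comparisons)."""
    corr = np.full((k, k), 0.5)
    np.fill_diagonal(corr, 1.0)
    fam = 0
    for rep in range(n_rep):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3, rep]))
        groups = rng.normal(size=(k + 1, m))
        df = (k + 1) * m - (k + 1)
        s2 = float(((groups - groups.mean(axis=1, keepdims=True)) ** 2).sum() / df)
        t = (groups[1:].mean(axis=1) - groups[0].mean()) / np.sqrt(2 * s2 / m)
        p, _ = dunnett_pvalues(t, corr, df, seed=seed, log2_n=12)
        fam += bool((p <= alpha).any())
    return fam / n_rep


# ---------------------------------------------------------------------------
# guild decline recovery and CI coverage
# ---------------------------------------------------------------------------

def guild_recovery(n_rep: int = 200, seed: int = 0,
                   declines: dict[str, float] | None = None,
                   n_sites: int = 16, n_draws: int = 10_000) -> dict:
    """Recovery of encoded per-guild declines at the study's design scale.

    Simulates ``n_rep`` survey series (16 sites, 9 year bins by default)
    with the requested proportional declines in the 2010 bin, refits the
    delta model per guild and measures (a) the distribution of recovered
    percent changes and (b) how often the 95% Monte Carlo CI covers the true
    index.  Bins inestimable in a replicate (e.g. a guild present in every
    survey of a bin) are excluded, conditioning on estimability.
    """
    declines = dict(RECOVERY_DECLINES if declines is None else declines)
    params = synthetic.disturbance_scenario(declines, "2010").apply(
        synthetic.guild_scenario_params(guilds=list(declines)))
    bins = [PRE_BIN] + [str(y) for y in range(2010, 2018)]
    truth = {sp.guild: {b: synthetic.truth_for(sp, b)[2] for b in bins}
             for sp in params}

    pct: dict[str, list[float]] = {g: [] for g in declines}
    cover = tot = 0
    for rep in range(n_rep):
        design = synthetic.generate_design(
            n_sites=n_sites, seed=300_000 + seed * 7919 + rep)
        com = synthetic.generate_community(design, params,
                                           seed=400_000 + seed * 7919 + rep)
        m = com.matrix
        for sp in params:
            dens = m.densities[sp.taxon]
            bfit = fit_binomial((dens > 0).astype(int), m.meta)
            lfit = fit_lognormal(dens[dens > 0], m.meta)
            series = monte_carlo_index(bfit, lfit, n_draws=n_draws,
                                       seed=seed * 7919 + rep, taxon=sp.taxon)
            if PRE_BIN in series.table.index and "2010" in series.table.index:
                pct[sp.guild].append(percent_change(series, PRE_BIN, "2010"))
            for b, row in series.table.iterrows():
                tot += 1
                cover += row["ci_lo"] <= truth[sp.guild][b] <= row["ci_hi"]

    out = {"coverage": cover / tot, "n_cells": tot, "guilds": {}}
    for g, d in declines.items():
        a = np.asarray(pct[g])
        out["guilds"][g] = {
            "target_decline_pct": 100 * d,
            "mean_recovered_decline_pct": float(-a.mean()),
            "lo": float(-np.percentile(a, 97.5)),
            "hi": float(-np.percentile(a, 2.5)),
            "n": int(a.size),
        }
    return out


def total_density_decline(n_rep: int = 30, seed: int = 0,
                          decline: float = 0.62, n_sites: int = 16,
                          n_draws: int = 10_000) -> float:
    """Mean recovered percent decline of the total-density index when every
    guild declines by the same fraction (the community-wide scenario)."""
    guilds = list(synthetic.GUILDS[:8])
    params = synthetic.disturbance_scenario(
        {g: decline for g in guilds}, "2010").apply(
        synthetic.guild_scenario_params(guilds=guilds))
    vals = []
    for rep in range(n_rep):
        design = synthetic.generate_design(
            n_sites=n_sites, seed=500_000 + seed * 7919 + rep)
        com = synthetic.generate_community(design, params,
                                           seed=600_000 + seed * 7919 + rep)
        total = com.matrix.densities.sum(axis=1)
        lfit = fit_lognormal(total[total > 0], com.matrix.meta)
        if total.min() > 0:
            # total density is present in every survey: the presence factor
            # is identically 1 and the index reduces to the density stage
            ratio = np.exp(lfit.lsmeans["2010"] - lfit.lsmeans[PRE_BIN])
            vals.append(100.0 * (1.0 - ratio))
            continue
        bfit = fit_binomial((total > 0).astype(int), com.matrix.meta)
        series = monte_carlo_index(bfit, lfit, n_draws=n_draws,
                                   seed=seed * 7919 + rep, taxon="total")
        if PRE_BIN in series.table.index and "2010" in series.table.index:
            vals.append(-percent_change(series, PRE_BIN, "2010"))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def closed_form_checks() -> dict:
    """Shannon/Pielou identities and hand-computed Bray-Curtis values."""
    from .survey_io import CommunityMatrix

    def mat(rows, taxa):
        ids = [f"x{i}" for i in range(len(rows))]
        meta = pd.DataFrame(
            [{"site": "S0", "year": 2011, "month": 7, "year_bin": "2011",
              "depth_m": 30.0, "longitude": -86.0, "area_m2": 200.0}] * len(rows),
            index=ids)
        reg = pd.DataFrame({"guild": ["reef planktivore"] * len(taxa),
                            "schooling": False}, index=taxa)
        return CommunityMatrix(
            densities=pd.DataFrame(rows, columns=taxa, index=ids, dtype=float),
            meta=meta, registry=reg)

    uni = indices(mat([[10.0] * 4], list("abcd")))
    bc = bray_curtis(mat([[2.0, 0.0], [0.0, 2.0]], ["a", "b"]), dummy_density=1.0)
    zz = bray_curtis(mat([[0.0, 0.0], [0.0, 0.0]], ["a", "b"]), dummy_density=1.0)
    return {
        "uniform_H": float(uni["H"].iloc[0]),
        "uniform_H_expected": float(np.log(4)),
        "uniform_J": float(uni["J"].iloc[0]),
        "bray_hand_value": float(bc.values[0, 1]),
        "bray_hand_expected": 100 * 4 / 6,
        "bray_zero_zero_with_dummy": float(zz.values[0, 1]),
    }
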