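# reeftrend

Reef-fish community impact analysis from ROV transect surveys.

Monitoring programmes that count reef fishes on fixed video transects need a
way to ask, after a large disturbance: did community structure change, which
trophic guilds and species drove the change, and have they recovered?
`reeftrend` implements the full analysis chain for that question, for
ecologists working with repeated remotely-operated-vehicle (ROV) surveys of
natural reefs:

1. **Ingestion** — per-transect counts are summed per survey (with a
   school-minimum override for actively schooling species prone to double
   counting), converted to densities by the surveyed area
   (n_transects × 25 m × field width), aggregated to trophic guilds, and
   binned into a pooled pre-disturbance baseline plus calendar years.
2. **Community structure** — densities are log(x+1) transformed, a dummy
   taxon at density 1 is appended (so depauperate samples have a defined
   dissimilarity), and pairwise Bray–Curtis dissimilarities
   d(a,b) = 100·Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ) feed a PERMANOVA with a mixed nested
   design: year (fixed), month within year and site within month within year
   (random), with z-scored depth and longitude covariates entered first.
   Pseudo-F denominators follow expected-mean-square rules; p-values come
   from Freedman–Lane permutation of reduced-model residuals with
   whole-block permutation at the denominator level, and exact enumeration
   for small problems.  Post-hoc pairwise year tests report
   t = √(pseudo-F) and mean within/between-year dissimilarities.
3. **Diversity trends** — per-survey species richness S, Shannon–Weiner
   H′ = −Σ pᵢ ln pᵢ and Pielou J′ = H′/ln S are modelled with linear mixed
   models (year bin fixed, site random intercept, covariates), followed by
   Dunnett many-to-one comparisons against the baseline (quasi-Monte Carlo
   multivariate-t adjustment).
4. **Standardized density indices (delta approach)** — per guild or species,
   a binomial GLMM models presence/absence and a lognormal mixed model
   models density-when-present; back-transformed least-squares means are
   multiplied into an index, with 95% CIs from 10,000 Monte Carlo draws on
   the link scales (with correlation injection between sub-model deviates
   when their annual least-squares means are correlated at Pearson
   p ≤ 0.05).  Species enter if their frequency of occurrence exceeds 5%
   before or after the disturbance.
5. **Synthetic surveys** — a generator produces zero-inflated lognormal
   communities over a realistic survey calendar with known parameters and
   disturbance scenarios that encode exact proportional index declines, so
   every stage has a parameter-recovery and calibration test surface.

## Worked example

Simulate a 16-site, 2009–2017 survey series in which herbivore density
declines by 96% in 2010, then recover that decline with the delta index:

```python
import reeftrend as rt

design = rt.generate_design(n_sites=16, seed=1)
params = rt.disturbance_scenario({"herbivore": 0.96}, "2010").apply(
    rt.guild_scenario_params())
community = rt.generate_community(design, params, seed=2)
m = community.matrix

dens = m.densities["guild:herbivore"]
bfit = rt.fit_binomial((dens > 0).astype(int), m.meta)
lfit = rt.fit_lognormal(dens[dens > 0], m.meta)
series = rt.monte_carlo_index(bfit, lfit, seed=5, taxon="herbivore")
print(series.table[["index", "ci_lo", "ci_hi"]].round(3))
print("decline pre-DWH -> 2010: %.1f%%"
      % rt.percent_change(series, "pre-DWH", "2010"))
```

prints

```
         index  ci_lo  ci_hi
bin
pre-DWH  2.055  1.337  3.034
2010     0.092  0.046  0.162
2011     1.796  1.130  2.707
...
2017     2.478  1.299  4.248
decline pre-DWH -> 2010: -95.5%
```

The index is occupancy × median positive density in individuals per 100 m²;
the 2010 bin drops from 2.06 to 0.09 — a recovered decline of 95.5% against
the encoded 96% — and returns to baseline afterwards, with 95% Monte Carlo
CIs around each point.

The same chain runs end-to-end from the command line, writing per-stage CSVs
and a checksummed manifest:

```sh
reeftrend all --outdir out --seed 1
```

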