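# Methods

## Data model and units

A *sample* is one ROV survey: 3–4 orthogonal 25-m transects at a reef site
on a date.  Counts are summed across transects; for schooling taxa a
school-minimum estimate, when recorded, supersedes the transect sum (the sum
double-counts mobile schools).  Abundance is divided by the surveyed area
`n_transects × 25 m × field_width_m` and reported as individuals per
100 m².  The transect field width is not a property of the count tables, so
it is an explicit parameter (`field_width_m`, default 2 m); because all
downstream quantities are ratios or within-model contrasts, the constant
cancels, but the unit is recorded in every output.  Taxa above species level
are dropped at ingestion unless the registry maps them into a merged group
(visually indistinguishable species pairs are handled this way).

Surveys are binned into a pooled pre-disturbance baseline ("pre-DWH": 2009
plus early-2010 surveys before the cutoff date, default 2010-06-01) and
calendar years 2010–2017.  The generator labels bins directly from the
calendar rather than simulating oil-arrival dates.

## Community structure

Densities are log(x+1) transformed to damp abundant taxa, then a dummy taxon
is appended at value 1 *after* the transformation (the natural reading of
"dummy at density 1" entering the resemblance computation; switchable via
`dummy_density`).  Bray–Curtis dissimilarity is computed on the 0–100 scale;
the dummy gives empty samples a defined dissimilarity (two empty samples are
identical) and bounds all values below 100.

PERMANOVA partitions the Gower-centred matrix G = J(−D²/2)J by sequential
(order-of-entry) sums of squares — covariates first (Depth, Longitude), then
Year, Month-within-Year, Site-within-Month-within-Year — via orthonormal
increments of the design subspaces; `tr(PG)` plays the role of the ANOVA sum
of squares and handles semi-metric dissimilarities through signed
eigen-coordinates.  Pseudo-F denominators follow expected-mean-square rules
for the mixed design: Year over Month/Year, Month/Year over Site/Month/Year,
Site/Month/Year and covariates over the residual.  When a trailing term
saturates the design (one survey per site-month cell, the common case), it
is confounded with the residual and dropped with a warning, and denominators
fall back to the residual.

Permutation p-values use Freedman–Lane permutation of residuals under a
reduced model.  Two refinements matter for nested designs:

* the reduced model excludes, besides the tested term, every term whose
  column span *contains* the tested term (a factor nested inside year spans
  the year dummies and would otherwise carry the year signal through the
  permutation unchanged); containment is detected numerically from the
  design matrices;
* residual rows are permuted in whole blocks at the level of the
  denominator term (months within years for the Year test), restricted to
  blocks of equal size; when the denominator is the residual, samples are
  permuted freely.

Ties are counted with the p = (b+1)/(m+1) convention; the full permutation
group is enumerated instead when it has ≤ 20,000 elements, giving exact
p-values (verified against brute-force enumeration at n = 6).  The default
is 9,999 random permutations.  Null simulations (no year effect, 500
replicates) put the Year-test rejection rate at α = 0.05 inside the exact
binomial interval; note that the test's resolution is limited by the number
of month blocks, so designs in which an affected year is a single month
cannot yield small p-values.

Pairwise year comparisons are two-level PERMANOVAs on the subset
(t = √pseudo-F) plus mean within- and between-bin dissimilarities taken
directly from the matrix entries, reported in a square table with within-bin
means on the diagonal.

## Diversity trends

Per-survey S, H′ (natural log — the base is a free choice and J′ = H′/ln S
is base-free) and J′ (undefined below two taxa, reported missing) are
modelled by REML linear mixed models: year bin fixed, site random intercept,
z-scored depth/longitude covariates (on by default for consistency with the
PERMANOVA; switchable).  Total fish density is modelled on the log scale for
variance stabilization and back-transformed at reporting time.  Month is not
a factor in these models.  Adjusted per-bin means are predictions at
covariate z = 0; the residual degrees of freedom are approximated as
n − p − (sites − 1), a deliberately simple choice in place of Satterthwaite.
A site variance estimated at the boundary (≈0) is retained and flagged.

Dunnett many-to-one comparisons take the contrast t-statistics and their
model covariance, and evaluate the joint two-sided tail of the multivariate
t by scrambled-Sobol quasi-Monte Carlo (2¹³ points by default, fixed seed);
adjusted p-values are clamped to be at least the raw p and are monotone in
|t| by construction.  The implementation agrees with the independent
one-way Dunnett procedure in scipy to ~1e-3 and holds the familywise error
within the binomial interval of 0.05 over 1000 null replicates.

## Delta-approach standardized indices

Species-level analysis is gated by a frequency-of-occurrence filter: a taxon
enters if it occurs in >5% of surveys either before or after the
disturbance.  Guild-level fits use guild-summed densities per survey; a
highly variable schooling member can be excluded from its guild sum via
configuration.

Each guild/species gets two sub-models with year bin fixed, site random
intercept, and z-scored covariates:

* **binomial (logit)** for presence/absence, fit by direct maximum
  likelihood with the site intercept integrated by 25-node Gauss–Hermite
  quadrature (the marginal likelihood factorises over sites); standard
  errors from the central-difference Hessian.  Bins with all-absent or
  all-present surveys are flagged inestimable and their surveys excluded;
  the logit-scale site SD is capped at 5 (beyond that the model is
  indistinguishable from per-site separation).  When the variance component
  sits at its boundary the β covariance is taken from the β block of the
  Hessian.
* **lognormal**: REML mixed model on ln(density) over surveys where the
  taxon was present (strictly positive input is a contract; the +1 shift is
  used only in the resemblance analysis).  Bins with a single positive are
  estimable with pooled-variance SEs and flagged "thin".

Least-squares means are predictions at covariate z = 0 and random effect 0
(median site) per bin.  The index is
`invlogit(μ̂_binom) × exp(μ̂_logn)` — occupancy × **median** positive
density, because Monte Carlo draws are back-transformed directly with no
lognormal mean correction; recovery tests target that estimand.  CIs are
the 2.5/97.5 percentiles of 10,000 draw products `μ̂ + σ̂·X` per link scale.
When the Pearson correlation between the two sub-models' annual
least-squares means has p ≤ 0.05, the lognormal deviates are replaced by
`r·X_binom + √(1−r²)·X_indep` — a Gaussian correlation injection chosen as
the concrete reading of "adjusted deviates" (switchable off).  Sub-model
Dunnett contrasts use the pre-disturbance bin as reference when estimable,
otherwise the first estimable bin (the invader pattern); only bins with
estimates enter the contrast set.

## Synthetic data generator

The generator draws a survey calendar (site depth/longitude fixed per site;
uneven month coverage mirroring the study: spring/summer/fall early on,
summer-only later; 3–4 transects per survey) and, per taxon, occurrence from
Bernoulli(invlogit(η)) and density-when-present from a lognormal, with
year-bin offsets, shared depth/longitude slopes, and independent site
intercepts (SD `site_sd`) on each link scale.  Random streams are split per
taxon by a stable hash, so adding a taxon never perturbs the others.
Integer counts for the ingestion path are Poisson draws with mean
density × transect area.

Disturbance scenarios solve the year offsets analytically so the
occupancy × median-density product declines by exactly the requested
fraction at the median site and mean covariate; the split between stages is
`occupancy_share` (default 0 — the guild-level pattern of interest is a
density-when-present decline).  For guild-level recovery studies each guild
is simulated directly as one zero-inflated lognormal aggregate (the exact
form the sub-models assume), with occupancy 0.7 — often but not always
present, keeping both stages identifiable.  The multi-species community set
spans all nine guilds with occupancies 0.08–0.71 and mild gradients.

What the generator does **not** emulate: spatial autocorrelation between
sites, within-school size structure, seasonal (month) effects (available
only as an optional offset hook), species interactions, and
detection/visibility error.  Passing recovery tests therefore show the
estimators are correct under the assumed zero-inflated lognormal process,
not that the process captures every feature of real survey data.

## Validation experiments and sizes

* Oracle equivalence: one-way Euclidean pseudo-F vs classical ANOVA F
  (n ≤ 30, agreement to 1e-10); exact enumeration at n = 6 vs brute force.
* Null calibration: 500 community simulations (6 sites × 3 years × 4
  months, 199 permutations) for the PERMANOVA year test; 1000 one-way
  layouts (8 comparisons) for the Dunnett familywise rate.
* Recovery: 200 series at the study scale (16 sites, 9 bins, ~270 surveys)
  with guild declines 96/87/82/64/73%; the replicate 95% interval of the
  recovered percent change covers each target, and Monte Carlo CI coverage
  of the true index is 93–97% pooled over guilds and bins.  Replicate bins
  that are inestimable (a guild present in every survey of a bin) are
  excluded — estimates are conditioned on estimability, never fabricated.
* The community-wide scenario (every guild −62%) recovers the total-density
  decline via the density stage (total density is present in every survey,
  so the presence factor is identically 1).

These sizes are the package's own accuracy/compute trade-off; the same
functions accept larger sizes.

## Known limitations

* The binomial GLMM uses non-adaptive Gauss–Hermite quadrature; with very
  large site SDs or tiny sites-counts the marginal likelihood flattens and
  affected bins are flagged rather than estimated.
* Degrees of freedom for mixed-model contrasts are approximated, not
  Satterthwaite/Kenward–Roger; with ≥ 10 sites and > 100 surveys the effect
  on Dunnett p-values is negligible (verified against lme4/scipy oracles).
* Sequential sums of squares make the PERMANOVA table order-dependent by
  design (covariates first); reordering terms changes SS attribution.
* The pairwise year tests do not partial out covariates (they are two-level
  tests on the subset), matching the post-hoc role they play.
* MS values in the PERMANOVA table are always SS/df.
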