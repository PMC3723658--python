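# Methods

`nestlingqg` estimates the genetic architecture of nestling plumage
colour from a cross-fostered full-sib dyad design. This note documents
the statistical model, the synthetic-data generator, the numerical
choices and the known limitations.

## The design and the model

In a cross-fostering experiment, nests are paired into **dyads** and half
of each brood (rounded down) is swapped between the two nests shortly
after hatching. Because full-sib families are thereby split across two
rearing environments, the resemblance among nest-mates decomposes into a
**nest-of-origin** component O (genetic plus early maternal effects), a
**nest-of-rearing** component R (post-swap common environment) and a
**dyad** component D (pair-level environment: site, year micro-habitat).
One nest per dyad additionally receives a brood-enlargement treatment,
which enters as a fixed effect.

The observation model for nestling *i* is the Gaussian mixed model

    y_i = x_i'β + o_{origin(i)} + r_{rearing(i)} + d_{dyad(i)} + e_i

fitted in two forms:

* **Univariate** — fixed effects treatment, year and sex; one variance
  per random term (V_O, V_R, V_D) and one residual variance V_Res.
* **Bivariate** — the male and the female expression of the trait are
  treated as separate response streams (each nestling contributes to
  exactly one). The origin effect is a sexed pair per nest,
  (o_M, o_F) ~ N(0, G) with G = [[V_OM, COV_MF], [COV_MF, V_OF]];
  rearing and dyad effects have sex-specific variances without cross-sex
  covariance, and residual variances are sex-specific. A cross-sex
  residual covariance is structurally unidentifiable (no individual
  appears in both streams) and is fixed at zero; likewise the rearing
  and dyad blocks carry no cross-sex covariance because those
  parameters are weakly identified at realistic design sizes and the
  scientific questions concern the origin block only.

Fixed effects in the bivariate form are one intercept per sex stream
plus treatment and year coefficients shared across sexes. Reference
categories are fixed for reproducibility: control treatment, first year,
female sex.

## Derived genetic parameters

With unrelated families, the nest-of-origin variance approximates half
of the additive genetic variance (plus a quarter of dominance and any
maternal effects). Broad-sense heritability therefore uses the full-sib
×2 correction,

    H² = 2·V_O / (V_O + V_R + V_D + V_Res),

with sex-specific numerator and denominator in the bivariate form, and
the cross-sex genetic correlation is

    r_mf = COV_MF / sqrt(V_OM · V_OF).

Both are computed **per posterior draw** and only then summarised: the
posterior of a ratio is not the ratio of posterior summaries. This is
also why plug-in ratios of published component estimates need not equal
published point estimates of H² or r_mf. Point summaries report both the
posterior mean and the Gaussian-KDE mode (Scott bandwidth, 512-point
grid), since field reports rarely name their summary. Intervals are 95%
highest-posterior-density (HPD) intervals: the shortest contiguous
window containing ⌈0.95·n⌉ sorted draws.

Because conjugate sampling keeps every variance strictly positive,
variance HPD intervals can never cover zero and are unsuitable for
testing random-effect inclusion; that decision is made by DIC instead.
Covariances and correlations are unrestricted in sign, so r_mf is tested
with its HPD interval directly (does it exclude 0? does it exclude 1?).

## The Gibbs sampler

Priors are inverse-Wishart on every variance (co)variance block with
scale V = 1, covariance scale 0 and degree of belief ν = 1.002 (scalar
blocks reduce to inverse-gamma); fixed effects carry an improper flat
prior. The sampler is a systematic-scan block Gibbs:

1. the fixed-effect vector jointly from its Gaussian full conditional;
2. each random term's levels jointly given all other terms — the levels
   are conditionally independent, so the origin update is a vectorised
   2×2 solve per nest and the scalar terms are O(n) bincount updates;
3. each variance block from its conjugate inverse-Wishart full
   conditional (2×2 draws via Bartlett decomposition);
4. the conditional deviance, −2 log N(y | Xβ + Zu, R), stored per draw.

This per-term blocking has the same stationary distribution as a joint
location update and makes a sweep O(n), at the cost of somewhat higher
autocorrelation; the `autocorrelation` helper exposes chain mixing.
Default settings (60 000 sweeps, 10 000 burn-in, thinning 25) give
~2 000 weakly autocorrelated draws on study-scale data (~600 nestlings).
The replicated simulation studies use 4 000 sweeps, 1 000 burn-in,
thinning 6 (500 draws per fit): at those designs the posterior-mean
Monte Carlo error (~0.01 on r_mf) is an order of magnitude below the
between-replicate spread, so longer chains would not change the
aggregate results.

Numerical safeguards: the fixed-effect design must be full rank after
reference coding (single-level factors are dropped with a warning);
Cholesky failure of a conditional precision raises with a diagnostic;
inverse-Wishart draws require df > p − 1, which holds whenever a term
has at least one level.

**DIC.** Deviance is conditional on the sampled random effects (the
convention of the MCMC mixed-model framework this pipeline mirrors), so
DIC = D̄ + pD with pD = D̄ − D̂ and D̂ evaluated at the posterior means of
the location parameters (via the accumulated mean linear predictor) and
of the residual variances. For a fixed-effects-only Gaussian model pD
approaches the number of location parameters plus one, which the test
suite verifies against the closed form.

## The synthetic-data generator

No field data accompany the analysis, so the generator is a first-class
module emulating the study design: 25 dyads (50 analysis nests), per-nest
brood sizes Poisson with mean 12 constrained to ±1 within a dyad
(≈ 594 nestlings), sex i.i.d. Bernoulli(0.5), two study years assigned
at the dyad level, one enlarged nest per dyad (the fostered-in extra
nestlings are excluded from analyses and never emitted). Default trait
architectures use the bivariate variance-component estimates of the
emulated blue tit study for hue, saturation and brightness; fixed-effect
magnitudes are not published, so the defaults are modest shifts chosen
once to echo the reported significance pattern (males brighter and
yellower; enlargement depressing hue and saturation).

The origin effect is simulated **at the nest level** — one sexed pair of
values per origin nest — because a full-sib design cannot separate
additive, dominance and maternal components; simulating at the
resolvable level keeps the generator and the estimator aligned.
Consequences worth keeping in mind when reading test results:

* passing recovery tests show the estimator is calibrated for the
  design it assumes, not that real data meet the full-sib assumption;
* extra-pair paternity is modelled by redrawing the whole origin effect
  for a random ~8% of nestlings (a conservative simplification of
  half-sib misassignment), which biases origin variance and r_mf
  downward as expected, but does not reproduce the exact half-sib
  covariance structure;
* rearing and dyad effects are drawn independently per sex, matching
  the bivariate model's diagonal blocks; real common-environment
  effects are likely positively correlated across sexes;
* no mortality, begging dynamics, measurement error hierarchy or
  multi-year pedigree structure.

All randomness flows from one seed through named substreams, so every
stage and every pipeline artifact is exactly reproducible.

## Simulation studies (the `studies` module)

* **Conjugate oracle** — with no random effects and a known residual
  variance the Gibbs draws are i.i.d. from the exact closed-form
  posterior; the largest coefficient-mean discrepancy is reported in
  Monte Carlo standard errors.
* **Recovery** — 100 replicates at 200 dyads × ~12 nestlings/nest with
  V_OM = V_OF = 1, COV_MF = 0.5, V_R = V_D = 0.5, V_Res = 10: the mean
  posterior mean of r_mf and the empirical coverage of the 95% H² HPD
  intervals (both sexes pooled). The single-replicate posterior-mean
  spread (SD ≈ 0.12) reflects genuine data-level uncertainty at this
  design, so recovery is judged on the replicate average.
* **Null behaviour** — 100 replicates at field scale (25 dyads) with
  COV_MF = 0: fraction of replicates whose r_mf HPD covers 0 and
  excludes 1.
* **DIC discrimination** — 50 replicates with a strong origin effect
  (V_O = 2, identical across sexes so the univariate model is correctly
  specified for it): fraction where the origin model attains lower DIC.
* **Prior robustness** — one well-identified dataset (100 dyads,
  r_mf = 0.8) refitted with the prior scale doubled; the qualitative
  significance flags are compared.

## Colour quantification

RGB readings from the sampling squares of an individual are averaged
per channel and converted with the standard hexcone model: brightness =
max/255, saturation = (max − min)/max, hue by 60°-sector chroma
arithmetic, in degrees [0, 360). Achromatic pixels have undefined hue
and are flagged NaN rather than 0 to avoid spurious clustering at red.
Repeatability of repeated measurements is the one-way ANOVA intraclass
correlation with the unequal-group-size coefficient k₀, truncated at 0.

## Known limitations

* Broad-sense H² here upper-bounds narrow-sense heritability: dominance
  and maternal components are partially absorbed into V_O.
* The bivariate r_mf posterior is prior-sensitive at small design sizes
  (ν = 1.002 places non-trivial mass near |r| = 1); the prior-doubling
  check guards the qualitative conclusions, not the point estimates.
* DIC magnitudes depend on the conditional-deviance convention; only
  differences between models fitted under the same convention are
  meaningful.
* The HPD routine assumes a unimodal posterior; for multimodal chains
  the shortest contiguous window is a summary, not a credible region.
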