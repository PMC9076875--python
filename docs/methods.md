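# Methods

This note documents the models and procedures `multidiv` implements, the
assumptions behind them, the synthetic study design used for validation, and
the numerical choices a user may want to audit or override.

## The analysis in one paragraph

Five organismal groups (vascular plants, bryophytes, invertebrates, fungi,
bacteria) are surveyed on ~110 plots ordered along a deglaciation
chronosequence.  Per-plot Shannon diversities are aggregated into the
rank-based **multidiversity** index mD; a Bayesian piecewise regression of
mD against time since deglaciation detects an assembly **threshold**; the
threshold splits the gradient into an early and a late successional stage;
stage-specific **path models** attribute group diversities to time (a proxy
for cumulative stochastic dispersal) and soil temperature (environmental
filtering), with residual covariance among groups read as a biotic-
interaction signal; **multi-betadiversity** contrasts community-wide
compositional dissimilarity between stages; **Moran's I** verifies that
model residuals carry no unexplained spatial structure.

## Diversity indices

**Shannon diversity** H = −Σ pᵢ ln pᵢ (natural log; the base is irrelevant
downstream because mD consumes only within-group ranks, but raw H output is
in nats).  Count tables (microbes, invertebrates) are rarefied before H:
each plot is subsampled without replacement to the minimum plot total
(default) and H is averaged over 999 iterations, correcting for unequal
sequencing depth / trapping effort.  Rarefaction uses raw counts, never
normalised tables.

**CSS normalisation** corrects microbial count tables for depth before
Bray-Curtis and occurrence weighting: each plot's counts are divided by the
cumulative sum of its counts up to the 0.5 quantile of its positive count
distribution (quantile configurable), then rescaled by the median scaling
factor so values stay count-like.  A single-taxon table degrades to
total-sum scaling with a warning.

**Multidiversity (mD)**: plots are ranked within each group by increasing H
(average ranks on ties, so tied plots cannot tilt a group's weight), the
per-plot mean rank across groups is min-max normalised to [0, 1].  mD is
invariant under any strictly monotone transform of a group's diversities —
the property that makes groups with very different absolute H commensurable.
Plots lacking a community in some group are a hard error by default;
`allow_missing=True` averages over available groups instead.

**Multi-betadiversity (mbD)**: per plot pair, the unweighted mean of the
five per-group Bray-Curtis dissimilarities (microbial tables CSS-normalised
first).  Stage summaries use within-stage pairs only, mirroring a split of
the community tables before computing dissimilarities.

The early-vs-late mbD contrast is tested two ways: a Mann-Whitney U over
within-stage pair values (powerful, but pairs sharing a plot are dependent,
so its p-values are optimistic) and a plot-label permutation test (999
shuffles, seeded, +1-corrected p).  The permutation null is exchangeability
of plots.  When composition also turns over along the gradient and the
stages are contiguous, the permutation test is *conservative*: shuffled
pseudo-stages mix short- and long-gradient-distance pairs and overdisperse
the null.  It is exactly calibrated (type-I ≈ 5%, verified over 200 null
simulations in the test suite) when plots are exchangeable.  A restricted
permutation over contiguous split points was considered and rejected: the
early-minus-late difference has a deterministic span-driven trend in the
split position, so that scheme is not calibrated either.

## Threshold detection

Four models of mD(t) compete:

* m1 — constant;
* m2 — one linear trend;
* m3 — change point with an intercept jump and a new slope (abrupt
  threshold);
* m4 — joined broken stick, continuous at the change point (smooth
  threshold): y = a + b₁t for t ≤ cp, y = a + b₁cp + b₂(t − cp) after.

Likelihood is Gaussian.  Priors: cp uniform on the observed time range;
intercepts N(ȳ, 10·sd(y)); slopes N(0, 10·sd(y)/sd(x)); jump N(0, 10·sd(y));
σ half-normal with scale 2.5·sd(y).  An all-uniform variant (`prior=
"uniform"`) flattens the linear block and σ.  These are weak on the scale of
the data; the cp prior is the only one with scientific content (no preferred
threshold location).

**Sampler.** Collapsed Metropolis-within-Gibbs: for fixed (cp, σ) the model
is linear-Gaussian, so the linear block is integrated out in closed form
(Woodbury identity on the marginal covariance) and only (cp, log σ) are
sampled by component-wise random-walk Metropolis.  Proposal scales adapt
toward 44% acceptance during burn-in only, so retained draws form a valid
Markov chain.  The linear coefficients are then drawn exactly from their
conjugate conditional for every retained iteration.  Protocol: 3 chains ×
11,000 generations, 1,000 burn-in (configurable).  Split R-hat and bulk ESS
are reported per parameter; R-hat > 1.05 raises a warning (or an error under
`strict_convergence`) — a diffuse cp posterior on data without a real
threshold legitimately trips this flag and must not abort a model
comparison.

**Model comparison** uses PSIS-LOO (arviz) on the stored pointwise
log-likelihoods, with Pareto-k diagnostics; if more than 20% of a model's
k exceed 0.7 its elpd falls back to exact leave-one-out refits (brute force
with reduced single chains, feasible at n ≈ 110).  **Bayes factors** for a
candidate cp use the Savage-Dickey density ratio prior(cp)/posterior(cp),
the posterior density estimated by Gaussian KDE over the pooled draws;
BF > 1 means the data moved mass away from the candidate.  **Segment fits**
are independent per-segment OLS (t, two-sided p, r² with df = n − 2); the
boundary plot belongs to the early segment.

## Path analysis

An observed-variable recursive path model per stage: exogenous drivers
(time, temperature; optionally pH, nutrients) → five group diversities
(mediators, residuals covarying freely pairwise) → mD.  All variables are
standardised per stage (each stage is its own model), so coefficients are
standardised betas.  Estimation is normal-theory ML on the sample
covariance: F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p minimised by L-BFGS-B from
regression-based start values (tolerance 1e−10); χ² = (n−1)·F_min.  For this
recursive structure with identical regressors per block, the ML point
estimates coincide with equation-by-equation OLS — used as an independent
oracle in the tests, never as the implementation.  Standard errors come from
the inverse numerical Hessian of F ((2/(n−1))·H⁻¹), Wald z tests two-sided
at α = 0.05 without multiplicity correction.

Mediator→outcome paths are estimated freely by default; a
`fixed_composite` mode fixes them to given weights for users who prefer to
treat mD as a built index.  Indirect effects are Σᵢ aᵢbᵢ per driver with
delta-method SEs from the joint parameter covariance and an optional seeded
bootstrap.  Fit indices: χ² p, CFI and TLI against an independence baseline
(free variances plus exogenous covariances), RMSEA with a 90% noncentral-χ²
confidence interval, SRMR as the RMS standardised residual (diagonal
included).  Stepwise pruning removes candidate drivers with no significant
direct or indirect effect, least significant first, refitting after each
removal; before a removal is accepted, a nested likelihood-ratio test
(candidate's directed paths fixed to zero, same variable set — removing the
variable from the model entirely would not be a nested comparison) can veto
it.

## Spatial diagnostics

Binary distance-band weights at 5 m and 10 m (row-standardisation and a
k-nearest-neighbour cap available but off by default).  Global Moran's I
with inference by 999 seeded permutations (analytic normality is avoided:
n is small and residuals can be skewed).  Plots without neighbours in a band
are excluded pairwise with a warning — with ~19 m median spacing the 5 m
band is mostly islands by design, and that is reported, not fatal.

## Synthetic study design (what the generator emulates)

Defaults mirror the field design: 110 plots, ages approximately uniform on
5-170 years, threshold at 60 years, transect spacing ~N(19 m, 6.3 m) with a
5 m floor, five groups with taxon richness {35, 18, 14, 90, 180}.  Group
diversity trajectories rise linearly before the threshold (0.02 nats/yr
from a baseline of 0.45·ln richness), are flat afterwards apart from a
temperature effect (0.1 nats per temperature SD, late stage only), and share
a single late-stage latent factor that induces pairwise residual correlation
0.4 among groups — the minimal mechanism for a positive community
covariance.  Temperature warms with age (0.02 °C/yr plus unit noise).

Taxa get Gaussian niche curves on the gradient (width 0.35·n plots, optima
evenly spread with jitter).  Each plot's composition is the niche profile
raised to a power solved by bisection so its Shannon entropy matches the
target trajectory exactly, then perturbed by lognormal noise (sd 0.6).
Applying noise *after* the entropy calibration keeps expected pair
dissimilarity independent of the evenness level to first order (proportional
noise contributes ≈ E|δ| regardless of the composition), which is what makes
the early and late stages exchangeable when the late co-structure is off.
The late co-structure itself is a taxon-level lognormal deviation shared by
all late plots (fraction 0.5 of the log-noise variance), which lowers
late-stage betadiversity without touching the early stage.  Counts are
multinomial draws at negative-binomial depths (invertebrates ~300, fungi
~4000, bacteria ~8000); plant and bryophyte covers scale a total cover that
grows from 5% to 95% across the gradient and are rounded to the 0.1% survey
resolution (rounding applies to the two visually surveyed groups only).
With `noise_sd=0` the generator emits exact expected abundances — the
deterministic limit used by the zero-noise recovery tests.

What the generator does **not** emulate: sequencing artefacts (chimeras,
compositional bias, zero inflation beyond multinomial sampling), 2-D spatial
community structure, within-season phenology, and taxon-specific responses
to temperature.  Passing tests therefore demonstrate correctness of the
estimators under a clean threshold-and-latent-factor world, not robustness
to every failure mode of real amplicon data.

Known approximations, found while validating and left as documented
behaviour:

* the per-plot entropy calibration couples taxa, so noiseless relative
  abundance curves are unimodal only up to ~2% of the peak height;
* the lognormal composition noise biases realized Shannon slightly
  downward at high evenness; at sd 0.6 the realized early-stage slope stays
  within 10% of the configured slope (the generator's stated contract);
* end-to-end, the rank transform plus the temperature-age correlation give
  the recovered threshold a tolerance of about ±12 years around the true
  60 — the recovered breakpoint *plot index* is typically 43-44 of 110.

Targeted simulators bypass the community layer where a check concerns a
single model: `simulate_broken_stick` (broken-stick mD with Gaussian noise;
defaults slope 0.01/yr, σ = 0.05) and `simulate_path_data` (a linear
recursive SEM with unit-variance variables, so coefficients are standardised
by construction).

## Problem sizes used in the checks

The test suite runs the full MCMC protocol (3 × 11,000) for every fitted
model; replicate-based checks use 20 seeds (threshold recovery, null
safety), 100 replicates at n = 500 (SEM bias/coverage), and 200 simulated
null datasets (permutation-test calibration).  `scripts/acceptance.py` runs
one complete pipeline at the default 110-plot design.  On one CPU the whole
suite takes roughly 10-15 minutes and the acceptance script under a minute.

## Limitations

* The sampler is specialised to Gaussian likelihoods and a single change
  point; time-series autocorrelation in mD is not modelled (Moran's I on
  residuals is the diagnostic offered instead).
* The SEM is observed-variable only (no measurement models) and assumes
  complete cases and multivariate normality for its standard errors.
* BIOM input is not supported; community tables are delimited text.
* The plot-label permutation test for mbD is conservative in the presence
  of gradient turnover (see above); the Mann-Whitney test is
  anti-conservative.  Report both, trust agreement.
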