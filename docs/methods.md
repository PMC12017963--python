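# Methods

This note documents the models, the synthetic-survey generator, the numerical
choices, and the limits of what passing tests demonstrate.

## The analysis chain

The package operationalises a survey-to-optimum chain for station × month
plankton ASV surveys: quality filtering and rarefaction; occupancy-based core
prioritisation with a Bray–Curtis contribution curve; trophic annotation and
profiles; alpha/beta diversity with kriged spatial surfaces; category- and
factor-level driver screening; and a hierarchical GAMM locating the
three-stressor (temperature, dissolved oxygen, nitrate) optimum of core
mixoplankton.

### Core selection

Each taxon gets an overall occupancy (fraction of all samples in which it is
detected, detection threshold one read) and a temporal occupancy (mean over
months of the fraction of stations detected within that month).  The rank
index is the mean of the two scaled occupancy ranks; ties break by mean
relative abundance, then by taxon id, so the ranking is deterministic.

For the contribution curve, the Bray–Curtis similarity between samples i and
j restricted to a taxon set S is `2·Σ_{t∈S} min(x_it, x_jt) / (N_i + N_j)`
with denominators over **all** taxa.  This makes per-taxon contributions
additive, so C(k) is an exact cumulative share of total similarity and is
nondecreasing by construction (renormalising within the subset would break
monotonicity).  The core is the top-k\* set where k\* is the last rank whose
relative gain exceeds the threshold (default 1%).  The threshold is
exclusive: a gain of exactly the threshold does not qualify (with a 1e-9
relative float guard), which is the reading under which both of the
documented worked examples hold; an absolute-gain variant is exposed via
`mode="absolute"`.

### Neutral model

Sloan's formulation: a taxon at mean relative abundance p is detected (≥ d
reads of Nt) with probability `1 − I_{d/Nt}(Nt·m·p, Nt·m·(1−p))`.  The single
parameter m is estimated by bounded least squares on occupancy; the 95% band
is a Wilson interval for the predicted detection proportion at the observed
number of samples.  d defaults to 1 read; Nt is the rarefaction depth.

### Diversity and kriging

Shannon entropy is in nats over the taxon subset of interest.  Seasonal
contrasts use Kruskal–Wallis followed by pairwise two-sided Wilcoxon rank-sum
tests with Benjamini–Hochberg adjustment.  Beta diversity uses Bray–Curtis
PCoA with the Lingoes correction (the additive constant keeps all axes real;
Cailliez would be the alternative) and a PERMANOVA whose p-value is
`(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, with exact enumeration whenever the
number of distinct label arrangements is below the permutation budget.

Kriging projects lon/lat to planar kilometres by equirectangular scaling at
the mean latitude (adequate over a small coastal domain), bins an empirical
semivariogram into 10 lags up to half the maximum separation, fits spherical,
exponential and gaussian models by weighted least squares with Cressie
weights n(h)/h², and keeps the best WLS score.  The semivariogram convention
is γ(0) = nugget.  The ordinary-kriging system is solved per node with a
Lagrange multiplier; weights are renormalised to sum to exactly one, which
also stabilises the near-singular systems a zero-nugget gaussian model can
produce (where the pseudo-inverse is used).  Validation is leave-one-out
re-prediction at the stations, summarised by Pearson r.  A caution
documented by the tests: a field with *exponential* covariance is too rough
at 24 stations for LOO r ≥ 0.9 no matter the range (the error-to-variance
ratio is scale-invariant around ~0.3); the smooth-field benchmark therefore
uses a squared-exponential field.

### Driver screening

VPA Hellinger-transforms the counts and computes the seven marginal/joint
redundancy-analysis R² values, each adjusted by Ezekiel's formula; the seven
Venn fractions follow by inclusion–exclusion, so raw fractions plus residual
sum to one identically.  Negative raw fractions are reported and clamped only
for display.  Default categories: Nutrient (6 variables incl. the N:P
ratio), Physicochemistry (8 variables), Geography (longitude, latitude); the
category map is an argument.

The partial Mantel statistic is the Pearson correlation of the two
off-diagonal distance vectors after both are residualised on the control
(default control: great-circle distance, the natural spatial confounder);
permutations shuffle rows/columns of the community matrix jointly and the
two-sided p has floor 1/(n_perm+1).

Random-forest importance follows the %IncMSE convention: regression trees on
explicit bootstrap samples (mtry = ⌊p/3⌋), per-tree percent increase in
out-of-bag MSE when one predictor is permuted, averaged over the forest.
sklearn's forest class does not expose per-tree OOB permutation importance,
so the forest is an explicit loop over `DecisionTreeRegressor`s with known
bootstrap indices.  Significance comes from refitting the whole forest on
permuted responses (default 100 nulls); p = (1 + #{null ≥ obs})/(1 + n_null).
At these settings the type-I rate at α = 0.05 is ≈ 5% by construction of the
permutation p-value, which the calibration tests confirm.

### The niche GAMM

The response (relative proportion over the three annotated trophic groups,
or a trophic ratio) is transformed log10(x + 1e-4); the pseudocount puts a
zero at −4, below any observed proportion at rarefaction depth 20,000.
Outliers are removed on the transformed scale (|z| > 3; a zero-variance
response removes nothing), and predictors are VIF-screened (warn above 5,
nothing dropped automatically).

The four hierarchical models are penalized-regression-spline additive models
(P-splines: cubic B-spline bases, second-order difference penalties,
sum-to-zero constraints absorbed by a null-space reparameterisation):

* M1: s(T) + s(DO) + s(N) + station random intercept
* M2: M1 + ti(T, DO);  M3: M2 + ti(T, N);  M4: M3 + ti(DO, N)

Tensor interactions are built from marginally-constrained bases, so they are
pure interactions excluding both main effects (the nesting M1 ⊂ … ⊂ M4 is
then by construction).  The station random intercept is a ridge-penalized
dummy block — the classical random-effect-as-penalty equivalence — and
population-level predictions set it to its zero mean, since the optimum
should be station-independent.  Defaults: 9 basis functions per main smooth,
5 per tensor margin.

Smoothing parameters minimise GCV (Nelder–Mead over log-λ, seeded from a
coarse shared-level grid).  Model comparison uses a small-sample corrected
Gaussian AIC whose penalty uses the alternative effective dof
2·tr(F) − tr(F²) (F the smoother-to-parameter matrix); the plain tr(F)-based
AIC selected a spurious tensor on purely additive data in roughly half of
replicate draws, whereas the corrected criterion keeps the base model ≥ 90%
of the time while still detecting a strong planted T×DO interaction in 20/20.
The optimum is the argmax of the selected model's population-level
prediction on a resolution³ grid (default 50) spanning the 2nd–98th
percentile box of each stressor; ties break to the lowest grid index and a
boundary argmax is flagged as a possible monotone response.  "Optimum" is
deliberately operationalised as the grid argmax of the predicted surface.

## The synthetic-survey generator

The generator emulates the structure of a sub-tropical coastal monitoring
programme: 24 stations sampled monthly for a year (288 samples), ~5000 ASVs,
a fixed per-sample depth of 20,000 reads (counts are allocated multinomially,
so the matrix is born rarefied and downstream stages are isolated from
rarefaction noise).

* **Environment.**  Temperature follows an annual sinusoid (≈ 10–28 °C)
  plus a fixed station offset (sd 0.8 °C) and jitter (sd 0.5); DO is
  anti-correlated with temperature (slope −0.35, noise sd 2.0, floor
  0.2 mg/L), giving corr(T, DO) ≈ −0.75 — strong but identifiable, since at
  |r| ≳ 0.95 the T×DO plane degenerates to a ridge and interaction surfaces
  extrapolate wildly.  Nutrients carry wet-season (Jun–Sep) enrichment with
  multiplicative station factors and lognormal noise.  All 14 variables are
  emitted; N:P is TN/TP.
* **Community.**  A planted core of 900 ASVs occurs per sample with
  probability 0.9 (non-core: 0.1).  Abundance weights are lognormal
  (σ = 0.2) with two realism features that are load-bearing for recovery:
  a bloom-dominance tail (50 core ASVs at ≈ 33× weight, lognormal σ = 0.1,
  restricted to the obligate groups so the planted mixoplankton response
  does not modulate their detectability) and a 0.4× abundance factor on
  non-core taxa (the abundance–occupancy relationship).  Together these keep
  per-present-taxon detection near 1, so the within-core occupancy ranking
  is sampling-noise-dominated and the last-1%-gain rule cuts near the
  planted core size; without a dominance tail an equal-share community puts
  the 1% knee near rank ~100 regardless of the true core size.
* **Trophic response.**  Taxa get one of three modes (54% / 24.6% / 21.4%
  autotroph / heterotroph / mixotroph).  The per-sample mixoplankton share is
  `0.45 · exp(−Σ((x_i − opt_i)/w_i)² + ε)`, ε ~ N(0, noise_sd = 0.1), with
  optimum (18.0 °C, 3.5 mg/L DO, 0.64 mg/L NO₃-N) and widths
  (10 °C, 6 mg/L, 1.0 mg/L); the heterotroph share is 0.35·(1 − mix) (so it
  moves oppositely) and autotrophs absorb the remainder.  The log-scale bowl
  makes the recovery target analytically clean for the log-linear GAMM.

**What the generator does not emulate**, and hence what passing tests do not
show about field data: sequencing error and chimeras; taxonomy-assignment
error (labels are exact); abundance-dependent detection biases beyond
multinomial sampling; spatial autocorrelation of community composition
beyond the environmental field; unbalanced designs and missing samples;
compositional coupling between trophic groups other than the planted
share model; and unknown/unannotated taxa (the tests for unknown handling
use hand fixtures).  Recovery results quantify the internal consistency of
the chain, not the accuracy of the published field estimates.

## Numerical choices and degenerate inputs

* Rarefaction is hypergeometric (without replacement); samples below depth
  are dropped and logged; zero cells stay zero.  Pipeline order is fixed as
  filter → rarefy.
* Contribution-curve pair sums are computed by a vectorised per-row sweep,
  O(n²·t) with n² pair weights 2/(N_i + N_j); equal row sums after
  rarefaction make the weights constant but the code does not assume it.
* The penalized system adds a 1e-10-scaled diagonal jitter before Cholesky;
  log-λ is clipped to [−15, 25].
* Ties in `locate_optimum` break to the lowest grid index (np.argmax).
* Seasonal mapping when no season column is supplied: Dec–Feb winter,
  Mar–May spring, Jun–Aug summer, Sep–Nov autumn.
* Per-stage seeds derive from the global seed by stage-name hashing
  (CRC32, modulo 2³¹−1), so single-stage reruns reproduce in isolation.
* Stochastic recovery metrics in `scripts/acceptance.py` (core
  precision/recall, the located optimum) are medians over three replicate
  surveys: the single-replicate recall has a small (~4%) failure probability
  driven by the rank of the last dominant core ASV, an order-statistic
  fluctuation, not an estimation error.

## Problem sizes

Default analyses run at the full synthetic design (288 samples × 5000 taxa).
Calibration suites use reduced but honest sizes chosen for desk-scale
verification: Mantel calibration at n = 20 with 199 permutations × 250
replicates; RF calibration at n = 60, 80 trees, 60 nulls × 15 replicates
(210 null tests); ladder selection rates over 20 seeds at n = 160.

## Known limitations

* The GAM's smooth p-values are approximate Wald tests on the penalized
  coefficient block; they are reporting aids, not selection criteria.
* GCV can undersmooth at small n; the corrected-AIC selection layer guards
  the ladder, but individual smooths may still wiggle.
* VIF warns rather than drops; with the default generator corr(T, DO) ≈
  −0.75 keeps VIF below the warning threshold's neighbourhood (~2–3), but
  strongly collinear field data will inflate optimum uncertainty along the
  collinear axis.
* Kriging assumes second-order stationarity and an isotropic variogram; no
  co-kriging with covariates.
* BIOM support is read-only HDF5 (BIOM 2.x); dense in memory after reading.
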