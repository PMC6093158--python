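# Methods

## Model

`rangedyn` models range change between two occupancy surveys of a ~5-km
grid as a persistence–colonization process. Conditional on the
first-survey state, each cell's second-survey occupancy is Bernoulli with

    q_i = φ_i X_i,t1 + γ_i (1 − X_i,t1),
    logit(φ_i) = φ0 + φd D_i + φh H_i,
    logit(γ_i) = γ0 + γd D_i + γh H_i.

Assumptions worth stating explicitly:

* **Detection is perfect.** Survey false negatives are assumed negligible
  (the underlying national surveys included a follow-up verification
  round); there is no occupancy/detection hierarchy.
* **Two surveys, one transition.** φ and γ are 25-year transition
  probabilities, not annual rates; nothing is inferred about dynamics
  within the interval.
* **Dispersal enters as a covariate, not a mechanism.** The neighborhood
  occupancy D (distance-weighted proportion of occupied cells within a
  radius) is a computationally cheap proxy for immigration pressure; it is
  not a dispersal kernel and carries no individual-level interpretation.
* **Habitat suitability is a fitted index.** H is the log-odds linear
  predictor of a first-survey logistic habitat model, evaluated on either
  epoch's environment. Using a first-survey fit to explain the transition
  is deliberate: the selection step asks which epoch's surface better
  explains the dynamics, which is informative precisely when the system is
  not at equilibrium.

The transition likelihood factorizes over the two first-survey strata
(occupied / empty), so the joint flat-prior posterior is the product of
two logistic-regression posteriors. This fact drives both the sampler and
an independent oracle in the tests (posterior medians vs two separate
logistic MLEs).

## Parameters and defaults

| parameter | units / domain | default | rationale |
|---|---|---|---|
| cell area | km² | 23.06 | ~351.8×10³ km² national coverage over 15,256 mesh cells; configurable per cell |
| dispersal radius | km | candidates {10, 25, 50, 75, 100} | the model-selection grid |
| dispersal weighting | exponent p ∈ {0,1,2} | candidates; `p=2` in examples | inverse-squared won in the reference analysis |
| autocovariate radius | km | {10, 25} | autologistic habitat variants only |
| MCMC | chains × iterations (+burn-in) | 3 × 1000 (+100) | mirrors the reference fit; tests raise/lower for stability/speed |
| projection replicates | count | 1000 (200 in the pipeline default) | Monte-Carlo error of per-cell frequencies ~0.016 at 1000 |
| potential-distribution threshold | frequency ∈ (0,1) | 0.1725, or derived | the published 95%-sensitivity cutoff; the pipeline can re-derive it from the fitted q of observed presences |
| step years | calendar | 2028, 2053, 2078, 2103 | four 25-year steps from the 2003 survey |

Covariates enter unstandardized — snow cover period in days, land-use
proportions in [0,1], slope in degrees — so coefficients are directly
comparable with the published table (e.g. −0.036 per snow-cover day in
Hokkaido, +4.27 per unit forest proportion).

## Design choices where the method description was open

* **D is a normalized weighted mean with the focal cell excluded.** This
  keeps D ∈ [0,1] ("neighborhood occupancy" reads as a proportion), makes
  slopes comparable across radii, avoids d=0 singularities, and prevents a
  cell from reinforcing itself. Cells with no neighbor inside the radius
  get D = 0 (no immigration pressure) with a logged warning.
* **Distances are planar Euclidean on projected km coordinates.** At 5-km
  resolution the projection error is far below the grid scale; geodesy
  would add a dependency without changing any result.
* **Temporal interpolation of land-use series** uses inverse
  distance-in-time weights over *all* census years, exact at observed
  years, never extrapolating outside the observed range.
* **WAIC is reported per observation on Watanabe's original scale**,
  −(Σᵢ lppd_i − Σᵢ p_waic_i)/n, with the variance form of p_waic. On this
  scale a Bernoulli model at chance scores ln 2 ≈ 0.693 and a weakly
  parameterised model coincides with deviance/(2n), which is the scale of
  the published ranking table (≈0.33 at deviance ≈10,019, n=15,256).
  Multiplying by 2n recovers the −2(lppd − p_waic) convention; rankings
  are unaffected.
* **Rhat is the classic (non-split) Gelman–Rubin statistic**
  √(((n−1)/n·W + B/n)/W), reported per parameter; a fit is flagged (not
  failed) when any Rhat exceeds 1.1.
* **The sampler is a blocked random-walk Metropolis.** Because the
  likelihood separates by stratum, the φ block is accepted against the
  occupied stratum's likelihood only, and the γ block against the empty
  stratum's. Proposal covariance is 2.38²/3 times the stratum MLE
  covariance; chains start overdispersed around the MLE. This mixes well
  enough that the 3×1000 default yields Rhat ≈ 1.00 and acceptance ~0.3;
  the contract is the posterior, not the algorithm.
* **Suitability-change decomposition is the linear-predictor block split.**
  ΔH_CL collects the snow terms (main effect + region interaction), ΔH_LU
  the land-use terms; intercept, region main effect, slope, and any
  autocovariate are epoch-invariant and cancel, so ΔH = ΔH_CL + ΔH_LU is
  exact (machine precision), not approximate. Cells are cross-classified
  by sign(ΔH) × dominant block; |ΔH_LU| = |ΔH_CL| ties (measure zero) go
  to the LU row and are logged. The association test uses the Yates
  continuity-corrected chi-square — on the published contingency table the
  corrected statistic rounds to the printed 12,697 while the uncorrected
  one gives ≈12,702.
* **The sensitivity threshold** is the largest cutoff retaining ≥95% of
  presence scores: with n presences, the ⌊0.05·n⌋-th order statistic from
  below. "Larger than the threshold" is strict (>) when accumulating
  potential-distribution area.
* **Projection RNG streams** derive from (seed, replicate index), so
  replicate counts can grow without reshuffling earlier replicates, and
  identical configs are bit-reproducible. The first step's D comes from
  the observed 2003 occupancy; later steps use the simulated state.
  Projection requires a habitat model without an autocovariate (the
  selected reference models had none); passing one is an error rather than
  silently freezing a stale autologistic term.
* **Group aggregation** uses order-statistic (lower/upper) percentiles for
  the 95% band, so ensembles of ≤40 members are spanned entirely — the
  appropriate reading for 1/9/4/36-member scenario groups.
* **Model-selection ties** (WAIC equal to float precision) break toward
  fewer habitat terms, then smaller dispersal radius.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the method assumes:

* regular 5-km grid with a northern region flagged as Hokkaido (default
  22% of rows);
* spatially autocorrelated fields built by Gaussian-kernel smoothing of
  white noise (the correlation length, default 50 km, is the kernel
  bandwidth — cheap, and adequate for covariates whose role is "smooth
  and autocorrelated", though not an exact Gaussian-process draw);
* snow cover period with a strong south→north gradient (≈15 → ≈180 days)
  and a 1978→2003 decline of ≈12 days; maximum snow depth co-varying with
  it;
* compositional land use via softmax of correlated fields (forest-
  dominated, closure < 1 with an implicit "other" class), drifting by
  suburban urbanization and rural abandonment through mass-conserving
  transfers;
* occupancy simulated from the *published* habitat coefficients and
  transition-parameter medians, so recovery tests have known generating
  values;
* scenario bundles (1 baseline / 9 land-use / 4 climate / 36 combined
  members) whose members differ in trend intensity multipliers (0.5–1.5),
  emulating slower/faster futures.

It does **not** emulate the real geography of Japan, observed census land
use, GCM snow fields, or the population-driven built-up-area model behind
the real land-use scenarios. Passing tests therefore demonstrate that the
*machinery* is correct and that parameters are recoverable under the
model's own assumptions — not that the published coefficient values are
right for Japan, which would require the original (non-distributable)
survey data.

Small-grid caveat: with the default 50-km correlation length, landscapes
much smaller than ~30×30 cells produce nearly constant covariate fields
and ill-conditioned habitat designs; tests on tiny grids shrink the
correlation length accordingly.

## Numerical choices

* Transition probabilities are clipped to [1e−12, 1−1e−12] inside the
  likelihood; pointwise likelihood values are floored at 1e−300 before
  logs, with a warning counter.
* WAIC at survey scale is accumulated draw-chunk-wise (mean likelihood
  per cell + Chan-et-al. combined variance of the log-likelihood) so the
  full draws×cells matrix is never materialised; the chunked path is
  tested to agree with the dense formula to 1e−10 relative.
* Logistic habitat fits use Newton MLE (statsmodels); perfect separation
  or an all-0/all-1 response is a hard error with a diagnostic naming the
  formula.
* Neighbor search uses a k-d tree with an exact distance filter
  (0 < d ≤ radius); the weight operator is a row-normalised sparse CSR
  matrix, so projection steps are sparse mat-vecs.

## Problem sizes used by the shipped checks

The test suite and acceptance script scale the study down where full size
adds nothing: survey-scale recovery runs on a 124×124 grid (15,376 cells,
mirroring the real 15,256); selection-consistency replicates use 45×45
(≈2,000 cells) with 6 structurally distinct candidates; the end-to-end
recovery sweep uses ten 64×64 replicates; scenario projections in the
acceptance script use 60×60 with 100 replicates per member. Worked
examples and CLI tests run on 12–45-cell-wide grids and the shipped
68-cell fixture.

## Known limitations

* No imperfect-detection layer; applying the model to surveys with
  substantial false negatives will bias φ and γ.
* φ and γ are epoch-scale; projections assume the 25-year transition
  structure holds stationarily for a century at the posterior-median
  point, ignoring posterior uncertainty (by design, to isolate scenario
  differences).
* The autologistic habitat variants are fitted and selectable but cannot
  be carried into projection (the reference analysis selected none).
* WAIC comparisons between candidates sharing the same data are subject
  to Monte-Carlo noise of order 1e−3 per observation at the default
  chain lengths; candidates whose dispersal fields correlate >0.99 are
  not reliably distinguishable at a few thousand cells — a property of
  the design, not the implementation.
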