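# Methods notes

This note documents the models behind `gcaconn`, the design decisions that
were genuinely open, what the synthetic cohorts do and do not emulate, and
the numerical conventions a user reproducing or extending results should
know about.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic cohort generator

Every stage of the pipeline is exercised against cohorts from
`gcaconn.synth`, where the generative truth is known.  The generator
emulates the features of a multi-site developmental neuroimaging study that
the analysis machinery actually depends on:

- **Nesting.** Subjects belong to families (sizes 1–3, default mix
  0.85/0.12/0.03; a configurable fraction of size-2 families flagged as
  twins), families to acquisition sites.  Families never straddle sites.
  SES is a family-level latent; GCA is individual.
- **Measurement.** 11 task scores follow a bifactor model (general +
  3 orthogonal domain factors, 4/4/3 assignment).  Equal loadings are solved
  in closed form so the population variance shares are exactly
  ω_h = 0.75 general, 0.13 specific, 0.12 unique.  Three SES indicators
  follow a one-factor model with squared loading 0.58; neighborhood
  disadvantage loads negatively because it is a deprivation index.
- **Connectivity.** A baseline correlation structure (within-network 0.30,
  between 0.05 in Fisher-z space), small per-site edge offsets (sd 0.02,
  configurable — no published value exists for site-effect variance, so a
  small nonzero default is used), and a handful of symmetric edge-space
  component maps whose per-subject expressions carry the planted signal.
  The first component's weight is
  `m = beta_g*gca + beta_s*ses + noise`; the others are nuisance
  inter-individual variation.
- **Motion.** Per-subject mean framewise displacement is truncated-normal
  (0.21 mm, sd 0.09, the study-population values this generator emulates);
  per-frame traces mix quiet gamma-distributed frames with a configurable
  fraction of >0.5 mm spikes whose frames get doubled amplitude, so the
  censoring stage has real work.  A config flag couples noise amplitude to
  motion for sensitivity analyses.
- **Covariates.** Age, sex, race are drawn from realistic margins,
  independent of the latents by default; `confound_covariates=True` couples
  them mildly so adjustment code paths can be exercised.

Two observation routes produce features:

1. **Time-series route** (`mode="timeseries"`): each subject's target
   edge-z matrix is back-transformed, repaired to the nearest symmetric
   positive-definite correlation matrix (eigenvalue clipping at 1e-4, then
   rescaling to unit diagonal), and frames are drawn from that covariance;
   the connectome module then censors, correlates, z-transforms and
   averages exactly as it would for real data.
2. **Edge route** (`mode="edges"`): Fisher-z features are written directly
   with Gaussian edge noise (sd 0.05, matching the sampling variability of
   roughly four censored 150-frame runs).  This is an observation model in
   its own right, used for the large-n mediation, null-calibration and
   cell-statistic studies where simulating frames adds only time.

**What the generator does not emulate:** spatial geometry of parcels,
scanner physics or preprocessing artifacts, heavy-tailed or autocorrelated
BOLD noise, non-Gaussian phenotype distributions, ordinal income/education
scales, and site differences in covariate composition.  Passing tests
therefore demonstrate that the *machinery* recovers planted effects under
idealized but realistically structured conditions — not that any particular
real dataset carries such effects.

### Calibration of planted effect sizes

The standardized SES→GCA path (default 0.32) is planted on the latent
variables: an OLS of `gca_latent` on `ses_latent` recovers it directly.

The brain-signal anchors — the brain–GCA correlation (default 0.42) and the
proportion of the SES→GCA effect mediated by the brain signal (default
0.155) — are planted on the **measured factor-score scale**, because that is
the scale on which such effects are estimated and reported: "GCA" in any
actual analysis is a factor score, not the latent factor.  The regression
factor score's validity (its correlation with the latent) is analytic —
√(λᵀΣ⁻¹λ), about 0.87 for the default battery and 0.90 for the SES triad —
and `synth.solve_brain_weights` inverts the measured-scale targets through
these validities to latent-scale generative weights, solving a scalar root
problem for the SES→brain weight so the planted proportion is hit exactly
in population terms.  Had the anchors been planted on the latents instead,
every downstream estimate would sit ~13% lower purely through measurement
attenuation, and recovery tests would be testing the attenuation arithmetic
rather than the pipeline.

With the default anchors the implied measured-scale mediation paths are
a ≈ 0.10 (SES→mediator), b ≈ 0.40 (mediator→GCA | SES), total ≈ 0.25.  At
n = 4000 the cohort-level sampling error of the recovered proportion is
roughly ±0.04 (the a-path is small, so its relative error dominates);
recovery tests therefore average over proportions and splits.

## Factor models

Both CFA fits minimize the ML discrepancy
F = log|Σ(θ)| + tr(SΣ(θ)⁻¹) − log|S| − t on the sample correlation matrix
(tasks standardized internally with training means/SDs), via L-BFGS-B with
an analytic gradient and a principal-component-based start.  Uniquenesses
are bounded below at 1e-3.

- **Heywood cases.** At fold-level sample sizes (n ≈ 150–250) a sizable
  fraction of bifactor fits legitimately reach the ψ ≥ 0 boundary (multiple
  restarts land on the same boundary optimum — these are true constrained ML
  solutions, not optimizer failures).  The default behavior is therefore the
  standard applied remedy: return the boundary-constrained solution with a
  warning.  `fit(heywood="raise")` turns the condition into an error naming
  the offending task, for users who want the strict diagnostic.
- **Scores.** Regression (Thurstone) weights Σ(θ)⁻¹λ on the model-implied
  matrix; test subjects are standardized with *training* statistics, making
  scores transferable without refitting.  Sign is canonicalized so each
  factor's loading sum is positive.
- **Fit indices.** χ² = (n−1)F, df = t(t+1)/2 − #params, RMSEA, SRMR, and
  CFI against the independence model.  On synthetic data these sanity-check
  correct specification; they are not comparable to any real dataset's
  values.
- The one-factor model with three indicators is just-identified; the ML
  solution coincides with the closed-form triad (λ₁² = r₁₂r₁₃/r₂₃ and
  cyclic), which the tests use as an oracle.  Factor counts and task→domain
  assignments are configuration inputs; no exploratory factor analysis is
  performed.

## Principal component regression and LOSO

- PCA is a mean-centered SVD with a deterministic sign convention (largest
  |loading| of each component positive).  Components are orthonormal, so
  all nested-k regressions reduce to one projection — this is what makes
  10,000-permutation streams tractable.
- k is chosen from the grid {5, 10, 25, 50, 100, 250, 500} ∩ [1, n−1] by
  five-fold CV within the training set; folds are family-blocked, PCA is
  refitted inside every inner fold, ties break toward the smaller k.
- Covariates (sex, race one-hot; age and mean FD centered at training means
  before squaring) are fitted on train and *applied* to test, never
  refitted.
- Cross-validated partial η² is defined as max(0, 1 − SSE_full/SSE_cov)
  with SSE_cov the residual sum of squares after covariates only and
  SSE_full after additionally subtracting the brain-based predictions.  No
  authoritative formula is published for this quantity; this definition is
  the one under which partial η² ≈ r_cv² for a well-scaled predictor, which
  matches how the two statistics are reported together in the literature
  (0.42² ≈ 0.176 ≈ 18%).  The invariant |η² − r²| ≤ 0.02 is asserted on
  synthetic runs.
- The headline LOSO statistic is the unweighted mean of per-fold
  correlations; a pooled-prediction correlation is logged as a diagnostic.

## Permutation inference

Exchangeability blocks implement three-level nesting: individuals shuffle
within families; whole families swap only with same-signature families
(size, twin status) within the same site; sites never mix.  The admissible
group size is ∏ m_sig! · ∏ size_f!, verified against brute-force enumeration
at small n.  Freedman–Lane residualizes the phenotype on covariates using
the whole sample, permutes residuals by admissible orderings, adds the fit
back, and reruns the per-fold stream.  Two fidelity/cost modes exist:

- default: reuse each fold's observed PCA basis and selected k.  The basis
  and the factor scoring are functions of the features and tasks only —
  y-independent — so the null distribution remains exact under the null.
- `reselect_k=True`: rerun inner k-selection per permutation (the fully
  literal re-run; orders of magnitude slower, available for spot checks).

The permutation p-value uses the add-one rule, so its resolution is
1/(n_perm+1).  Consequence for the 120-cell analysis: BH-FDR at q = 0.05
needs p ≤ k·0.05/120 for k discoveries, which 200 permutations can never
deliver; cell tests default to 1000 permutations (`n_perm_cells`), and the
global LOSO test keeps 200.

## Network cells, consensus maps, drop-one-network

Edge-level association is the standardized simple-regression β (equal to
the correlation between z-scored edge and covariate-residualized z-scored
phenotype); cells average |β|.  Cells with mean |β| > 0.03 are annotated as
"elevated" separately from significance.  Per-edge regression is the
primary definition throughout; deriving edge weights from the consensus map
instead is possible but not the default, since the two answer different
questions.

The consensus map regresses the phenotype on all k whole-sample component
expression scores (fixed covariates; random intercepts for family nested in
site via a linear mixed model) and sums coefficient-weighted component
maps.  If the mixed model fails to converge the fit falls back — with a
logged warning — to OLS with family-cluster-robust errors, which leaves the
coefficients, and hence the map, essentially unchanged.  Consensus uses a
single whole-sample PCA rather than per-fold bases: the map is a
descriptive summary, not an out-of-sample claim.

Drop-one-network removes every edge incident to the named network
(features drop from C(R,2) to C(R−m,2)) and reruns the entire LOSO stream.

## Mediation

Matched halving reimplements the balanced-halves contract directly: family
units are paired greedily by Mahalanobis distance over family-averaged
matching variables (family size included), pair members are assigned to
opposite halves at random, and a draw is accepted only when every matching
variable's |standardized mean difference| < 0.1 (up to 50 redraws).

The mediation engine fits two OLS regressions (mediator ~ treatment +
covariates; outcome ~ treatment + mediator + covariates) on z-scored
treatment/mediator/outcome, and draws coefficient vectors from each fit's
asymptotic normal (quasi-Bayesian, 1000 draws by default; with nested OLS
fits the total effect decomposes exactly as c = c′ + ab).  Two proportion
summaries are reported: the **point estimate** a·b/(a·b + c′) — the
headline, because it stays finite under weak signal — and the mean of
per-draw ratios (sign-discordant draws dropped with a logged count, ratios
clipped to [0,1]), whose percentile interval is the proportion CI.  The
ratio is only meaningful when the total effect is bounded away from zero;
with a near-zero total the per-draw ratios are unstable no matter the
estimator.

In the split-half stream the GCA and SES factor models are fitted in split
*a* and transferred to split *b* along with the PCR signature, so nothing
trained ever sees split *b*; site enters the split-*b* regressions as fixed
one-hot covariates.  Re-running with a single SES indicator as treatment
covers the indicator-level follow-up analyses without a dedicated code
path.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own desk scale: 60 parcels in 15 networks (4 per
network) keep the full 120-cell grid at 1770 edges; the main recovery
cohort is 10 sites × 100 subjects through the full time-series route; null
calibration uses 50 cohorts of 4 sites × 50–60 subjects at 20 parcels;
mediation recovery uses 4000 subjects at 30 parcels with 20 split pairs per
planted proportion; cell detection plants elevation in the 11 cells
involving the CP (cingulo-parietal) and RST (retrosplenial-temporal)
networks and checks recovery over 10 seeds.  The low-motion sensitivity
rerun rescales the per-site minimum (30 instead of 75) because a desk-scale
site holds ~45 low-motion subjects.

## Known limitations

- The bifactor fit assumes continuous, roughly Gaussian indicators;
  ordinal-indicator (polychoric) CFA is out of scope.
- Permutation reuse of the observed k (default) is slightly conservative if
  k-selection itself overfits; the `reselect_k` flag exists to quantify
  this at small scale.
- The mixed-model consensus fit builds one variance-component column per
  family and is not economical beyond a few thousand families.
- Proportion mediated is reported unclipped per split but is intrinsically
  unstable when the total effect is weak; interpret it only alongside the
  indirect-effect CI.
- No site harmonization of features is performed anywhere — site offsets
  travel through the PCA exactly as they would in the emulated analyses.
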