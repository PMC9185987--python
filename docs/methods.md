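# Methods

## The longitudinal model

The response of subject *i* at annual visit *t* (peak strain, LVEF, LVM, …)
follows a Gaussian linear model whose errors are first-order autoregressive
within subject:

    y_{i,0} ~ N(μ_{i,0}, σ_y²)
    y_{i,t} ~ N(μ_{i,t} + β (y_{i,t−1} − μ_{i,t−1}), σ_y²),   t ≥ 1
    μ_{i,t} = α_t + γ_loa loa_{i,t} + γ_ace ace_{i,t} + δ age_i⁰

There are no subject random effects: all within-subject dependence is
carried by the AR term. The covariate indicators have their own Bernoulli
marginals, loa ~ Bern(η_loa) and ace ~ Bern(η_ace), which serve two
purposes: they close the generative model for simulation, and they provide
the imputation distribution when an indicator is unobserved.

Priors are vague and proper: independent N(0, 100²) on each α_t, β, γ_loa,
γ_ace, δ and on log σ_y² (i.e. SD 100 on each), and Uniform(0, 1) on η_loa
and η_ace. A parameter is flagged significant when its equal-tailed 95%
posterior quantile interval excludes zero; the same rule applies to the
visit contrasts α_t − α_0, computed draw-wise.

## Posterior computation

A blocked Gibbs sampler, exploiting that the AR(1) model quasi-differences
into an ordinary Gaussian regression:

* **Location block** (all α_t, γ_loa, γ_ace, δ jointly). Writing x_{i,t}
  for the design row of μ_{i,t}, the transformed observations
  y_{i,t} − β y_{i,t−1} regress on x_{i,t} − β x_{i,t−1} (visit-0 rows
  untransformed) with iid N(0, σ_y²) errors, so the full conditional is
  multivariate normal and is sampled exactly via a Cholesky factor. Joint
  sampling keeps mixing fast even when an indicator is (nearly) collinear
  with the intercepts — the sampler then draws along the prior-regularised
  ridge instead of random-walking it.
* **β**: given the residuals e_{i,t} = y_{i,t} − μ_{i,t}, the innovations
  regress e_t on e_{t−1}; conjugate normal update. β is not constrained to
  (−1, 1): with a finite number of visits the likelihood is well defined for
  any β and the data keep it near its true value.
* **σ_y**: the prior is on log σ², which is not conditionally conjugate, so
  log σ² is updated by slice sampling (stepping-out + shrinkage, width 1).
* **η_loa, η_ace**: Beta(1 + s, 1 + n − s) with s the current sum of the
  indicator over all in-span cells (observed and imputed).
* **Missing covariates**: Bernoulli full conditional combining logit(η)
  with the likelihood terms in which the indicator's cell appears (its own
  visit and, through the AR mean, the following visit).
* **Missing responses**: a response missing from a subject's last observed
  visit onward contributes nothing to the observed-data likelihood under
  MAR — the AR chain factorises forward — so trailing missing visits are
  truncated, which equals exact marginalisation. A response missing
  *between* observed visits is a latent node with a Gaussian full
  conditional (precision (1 + β²)/σ² when both neighbours exist) and is
  imputed, preserving the stated consecutive-visit recursion without
  inventing a gap-adjusted kernel.

Initialisation: least squares with β = 0 for the location block, jittered
per chain; observed covariate frequencies for η. Defaults are 3 chains of
20 000 iterations with 5 000 burn-in and no thinning; convergence is
monitored with split-R̂ (arviz) and any parameter above 1.05 flags the fit
as non-converged via a warning — results are still returned, never silently
discarded. Intercept summaries are reported only through visit 5 by default
(few subjects extend further in the emulated design, so later intercepts
are weakly informed); all draws are retained.

Validation is by oracle equivalence and calibration rather than by
comparison with another sampler: the sequential log-likelihood equals the
joint multivariate-normal density built from the AR covariance recursion on
random small panels (10⁻⁸); with β and σ fixed the intercept draws match
the conjugate Gaussian closed form (Kolmogorov–Smirnov < 0.05 at 10⁴
draws); and across 50 replicate simulations (150 subjects × 4 visits,
2 chains × 3 000) the 95% intervals cover every generating parameter at a
rate inside [88%, 100%]. These sizes keep the whole battery to a few
minutes on one CPU while leaving the Monte-Carlo error of a coverage
proportion (≈ 3% at 50 replicates) well inside the acceptance band.

## Synthetic cohorts

The generator runs the model above forward, so fitter tests are true
parameter-recovery experiments. Defaults emulate the natural-history cohort
the package targets:

* 47 DMD subjects, up to 6 annual visits; optional cross-sectional controls
  with a single baseline visit.
* Baseline age truncated-normal 11.2 ± 3.1 years on [5.3, 18.1] (rejection
  sampling); controls 12.1 ± 4.1 on [6.0, 18.3].
* η_loa = 0.25 and η_ace = 0.59 — the observed fractions of non-ambulatory
  subjects and of ACE-inhibitor/ARB users in the emulated cohort.
* `loa_mode="monotone"` (default) makes indicators absorbing, since losing
  ambulation is clinically one-way; `"iid"` matches the model's independent
  Bernoulli draws exactly and is what all fitter tests use.
* Dropout: each subject leaves the study after Geometric(p) retained
  visits, so visit 0 is never lost; censoring is independent of the
  response, hence MAR by construction.
* Bundled parameter presets: `peak_strain_params()` (visit intercepts
  −17.9 … −14.9 %, β = 0.3, σ_y = 1.5 %) and `lvm_params()` (intercepts
  73.5 … 86.6 g, γ_loa = 6.5, γ_ace = −5.6, δ = 4.8 g/year, σ_y = 10 g).
  The residual SDs are not identifiable from published summary tables;
  1.5 % is consistent with the width of reported strain credible intervals
  at n ≈ 47, and 10 g is of the order implied by the LVM intervals —
  chosen once as realistic values and kept.
* Segmental strain-time curves use a raised-cosine contraction template
  (zero at end diastole, most negative at mid cycle), circularly shifted
  per segment by a phase offset, plus optional Gaussian noise. Any smooth
  unimodal template would do; this one is fixed and documented. Real strain
  curves have asymmetric systole/diastole timing and correlated noise —
  the generator does not emulate that, so passing tests demonstrate
  correctness of the *metrics*, not robustness to physiological waveform
  variety.

What the generator deliberately does not model: treatment dynamics (dose
changes, drug switching), informative dropout, measurement batch effects,
and imaging itself (tags, contours). Conclusions from simulation tests
transfer to real data only insofar as the model's assumptions (linear
covariate effects, homoscedastic AR(1) errors, MAR) hold there.

## Strain metrics and CURE

Segments follow the mid-ventricular AHA circumferential order (anterior →
anteroseptal → inferoseptal → inferior → inferolateral → anterolateral);
rows are reordered by label on construction so the spatial transform always
sees a consistent circumference. Contraction strain is negative throughout;
"peak" means most negative, and comparisons in reports are on signed values.

* Composite peak strain: mean of per-segment minima (each segment at its
  own peak time).
* Global strain: the across-segment mean at the systolic frame — the frame
  where that mean is most negative, earliest frame on ties. Global can
  never be more negative than the composite peak; equality holds when the
  segments peak together.
* CURE: per frame, the 6-point spatial DFT gives S0 (squared magnitude of
  the zeroth harmonic) and S1 (summed squared magnitudes of orders ±1);
  CURE = Σ_t S0 / Σ_t (S0 + S1). With six samples, spatial orders above 2
  alias, and only 0 and ±1 enter the index by definition. The ratio-of-sums
  form is the default because it is stable when individual frames carry
  near-zero strain; a per-frame-mean variant (mean of S0/(S0+S1) over
  frames with nonzero power) is available via `per_frame_mean=True`. Both
  give exactly 1 for a spatially uniform field and 0 for a zero-mean pure
  first harmonic. An all-zero field raises an error rather than returning
  an arbitrary value. One consequence of the 0/±1 definition worth knowing:
  an anti-phase *alternating* pattern around the six segments lives
  entirely in spatial order 3 and leaves CURE at 1 — CURE detects a single
  dyssynchronous arc, not every conceivable phase pattern.

## Cardiac indices

BSA uses the Mosteller formula √(height·weight/3600) — the dominant choice
in pediatric cardiology — with Du Bois available behind a flag; published
indexed tables cannot adjudicate the choice because they print means of
per-subject ratios. LVEF = 100·(EDV − ESV)/EDV. LVAPD averages the
available landmarks (septal, lateral, apical) within each long-axis view,
then averages the two views; a single available view is used alone with a
logged warning rather than an error, since real cohorts lose views to scan
quality. Which landmarks should enter is not standardised; all available
ones are averaged by default.

## Cross-sectional comparisons

Welch's unequal-variance t-test for two-group comparisons and one-way
ANOVA for three cohorts, both two-sided. The summary-statistics entry point
(mean, SD, n per group) is first-class because published baseline tables
are exactly that; the raw-sample path computes the summaries first, so the
two agree identically, and is cross-checked against scipy's Welch test.
Stars follow the 0.05/0.01/0.001/0.0001 convention.

## MCID

Distribution-based threshold: fraction (1/3 default, 1/2 stricter) of the
parameter's baseline SD, compared against the magnitude of the model-based
one-year change (posterior mean of α_1 − α_0); the boundary counts as
meeting the threshold. Thresholds at 1/2 SD are nested inside those at
1/3 SD, so the count of parameters meeting the MCID is monotone in the
fraction. The tracked parameter set (17: composite + global + 6 segmental
strains, CURE, LVAPD, LVEF, LVM/LVMI, LVESV/LVESVI, LVEDV/LVEDVI) is this
package's enumeration of the standard panel; anchor-based MCID methods are
out of scope.

## Known limitations

* The AR(1) recursion assumes equally spaced (annual) visits; irregular
  spacing would need a continuous-time autocorrelation kernel.
* σ_y is homoscedastic across visits and subjects; real strain variance
  likely grows with disease progression.
* Covariate imputation assumes the Bernoulli marginals are exchangeable
  across visits (no age trend in η), exactly as the model states.
* The fitter requires each subject's span of visits to be representable as
  consecutive annual indices; wholly missing early visits (no visit-0 row)
  are not supported.
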