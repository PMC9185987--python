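# dmdlv

Longitudinal modelling of left-ventricular (LV) function in Duchenne
muscular dystrophy (DMD), built around tagged-MRI circumferential strain.

Cardiomyopathy is the leading cause of death in DMD, yet it progresses
silently for years while the ejection fraction stays normal. Natural-history
studies therefore track more sensitive measures — segmental Eulerian
circumferential strain (ℇcc%), the CURE dyssynchrony index, BSA-indexed
volumes and mass, and atrioventricular-plane displacement (LVAPD) — over
annual MRI visits. This package implements the full desk-side analysis for
such a study: deriving the per-visit biomarkers, comparing groups
cross-sectionally, fitting the longitudinal trajectory model, and judging
clinical relevance of one-year changes. Because subject-level data from such
cohorts are rarely shareable, a synthetic-cohort generator with exactly the
model's statistical structure is a first-class component, so every stage is
testable and the whole pipeline runs end to end without any download.

## The model

For subject *i* at annual visit *t*, a Bayesian linear model with
first-order autoregressive errors:

```
y_{i,0} ~ N(μ_{i,0}, σ_y²)
y_{i,t} ~ N(μ_{i,t} + β (y_{i,t−1} − μ_{i,t−1}), σ_y²),   t ≥ 1

μ_{i,t} = α_t + γ_loa · loa_{i,t} + γ_ace · ace_{i,t} + δ · age_i⁰
loa_{i,t} ~ Bernoulli(η_loa),   ace_{i,t} ~ Bernoulli(η_ace)
```

α_t is the population response at visit *t* (so α_t − α_0 is the average
change from baseline), β carries the within-subject serial dependence,
γ_loa and γ_ace are the effects of loss of ambulation and of
ACE-inhibitor/ARB use, and δ is the effect per year of baseline age.
Priors are vague and proper: N(0, 100²) on every location parameter, β and
log σ², Uniform(0, 1) on η. The posterior is sampled by a blocked Gibbs
scheme (see `docs/methods.md`); a parameter is reported "significant" when
its equal-tailed 95% credible interval excludes zero. Missing responses and
covariates are handled by data augmentation under a missing-at-random
assumption.

Strain summaries from a 6-segment × frame matrix: per-segment peak
(most-negative) strain, their mean (composite peak ℇcc%), the
across-segment mean at systole (global ℇcc%), and CURE — the spatial
Fourier power ratio Σ S0 / Σ (S0 + S1) over frames, 1 = synchronous,
0 = a pure first-harmonic dyssynchrony pattern.

## Worked example

```python
from dmdlv import *

# Baseline group comparison straight from published summary statistics
t, df, p = welch_t(GroupSummary(-17.4, 2.3, 58),   # DMD peak strain
                   GroupSummary(-19.6, 0.9, 15))   # controls
print(f"Welch t = {t:.2f}, df = {df:.1f}, p = {p:.2e}")

# Simulate a DMD cohort from the published peak-strain trajectory and refit
cfg = SimulationConfig(params=peak_strain_params(), n_subjects=150,
                       n_visits=6, loa_mode="iid", seed=20)
fit = fit_model(simulate_cohort(cfg), "peak_strain_pct",
                mcmc=McmcConfig(n_chains=3, n_iterations=4000,
                                n_burnin=1000, seed=21))
for s in fit.summaries[:6]:
    print(f"{s.name:>8}: {s.mean:6.1f}{'*' if s.significant else ' '} "
          f"({s.ci_low:.1f}, {s.ci_high:.1f})")
print(trajectory_differences(fit)[-1].name, "...")

# Strain summaries for one visit, with a delayed half-circumference
tc = simulate_strain_timecourse([-19.4, -18.9, -17.1, -15.4, -18.6, -17.7],
                                n_frames=20, phase_offsets=[0, 0, 0, 4, 4, 4])
s = summarize_timecourse(tc)
print(f"composite peak = {s.peak_composite:.2f}%, global = "
      f"{s.global_strain:.2f}% (frame {s.systole_frame}), CURE = {s.cure:.3f}")
```

prints

```
Welch t = 5.77, df = 59.5, p = 2.99e-07
 alpha_0:  -17.9* (-18.5, -17.4)
 alpha_1:  -16.9* (-17.5, -16.3)
 alpha_2:  -16.9* (-17.5, -16.3)
 alpha_3:  -17.0* (-17.6, -16.4)
 alpha_4:  -15.8* (-16.4, -15.2)
 alpha_5:  -14.8* (-15.3, -14.2)
alpha_5-alpha_0 ...
composite peak = -17.85%, global = -16.15% (frame 12), CURE = 0.891
```

The baseline DMD/control strain difference is overwhelming (p ≪ 0.0001);
the refitted visit intercepts recover the generating trajectory (−17.9 at
baseline worsening to −14.9 at year 5, a 3.0-point absolute change); and
delaying half the circumference leaves the composite peak unchanged while
pulling global strain toward zero and CURE below 1 — the signature of
dyssynchrony.

A `dmdlv` command-line pipeline wraps the same functions:
`dmdlv simulate | derive | compare | fit | mcid | report` (see `--help`).

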