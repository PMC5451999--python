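# Methods

This note records the statistical model the package implements, the
choices that were genuinely open, the numerical details, and what the
synthetic-data experiments do and do not demonstrate.

## Model

Daily mean concentrations y (μg/m³) at stations s over days t are
modelled on the natural-log scale (concentration histograms are strongly
right-skewed, so the log restores approximate normality):

    y(s,t) = μ(s,t) + ε(s,t),  y ~ N(μ, σ²)
    μ(s,t) = f1(t) + f2(t) + Σᵢ s(xᵢ(s,t)) + Σₖ s(pₖ(s)).

Back-transform is plain exponentiation; no lognormal bias-correction
factor is applied, so predictions are medians rather than means of the
implied lognormal — a deliberate convention kept throughout.

### Temporal basis functions

The station × day log panel, after removing each station's own mean, is
decomposed by SVD; the first two right singular vectors are the temporal
basis.  Station-mean (row) centring is used because the goal is the
*shared* temporal shape: removing per-day means instead would subtract
exactly the signal of interest.  Signs are fixed so each component is
positive in mid-winter (day 15), making "high in winter" the positive
direction.  The raw vectors are smoothed by a natural cubic smoothing
spline parameterised by effective degrees of freedom (default 12 —
enough for two seasonal cycles, too stiff for day-to-day noise); the
smoother matrix is built by the classical band-matrix (Reinsch)
construction and λ is found by bisection on tr S(λ).  Gaps in the panel
are first filled by iterative truncated-SVD completion (rank 2 to match
the two retained components; tolerance 1e−6 on the relative change of
imputed entries; 500 iterations max; observed cells never change).

### Additive fitter

Smooth terms are cubic regression splines with interior knots at
training-data quantiles, each term limited to at most 10 degrees of
freedom to prevent overfitting; the wind vector enters as a single
bivariate tensor-product smooth (quadratic marginals, 8 df) because the
two components interact.  The model is solved by ordinary least squares
on the assembled basis (Gaussian response, identity link), which makes
every fit deterministic and fast enough for thousand-member ensembles;
AIC = n·log(SSE/n) + 2(p+1) with p the number of coefficients.
Prediction inputs outside the training range are clamped to the boundary
and flagged as extrapolation.  A rank-deficient design raises rather
than silently dropping columns.

### Covariate selection

Candidates are screened by variance inflation factors (VIF_j =
1/(1−R²_j); threshold 10, the conventional cut-off — the source method
names VIF but no value), then backward-stepwise elimination under AIC:
drop the single term whose removal most lowers AIC, stop when no removal
strictly lowers it.  Equal improvements drop the later-listed term.  An
empty final set is legal (with a warning).  A correlation screen is
provided for dropping site descriptors unrelated to the response (the
role GDP and elevation played in the original application), without a
fixed significance rule.

### Bagging

B bootstrap resamples of the rows (default B = 1000; tests and the
acceptance script use B = 25, which is enough for stable weighted means
at a fraction of the cost), one additive fit per resample.  Each
member's R² is computed on its own out-of-bag rows — the member never
scores rows it trained on — and weights are (R²ᵢ)²-proportional
(negative OOB R² is clipped to zero).  The out-of-bag *ensemble*
prediction of a training row renormalises the weights over the members
that left that row out; this plays the role of a 63.2/36.8% split
validation.  The ensemble SD uses the weighted form with the M/(M−1)
correction, M = number of nonzero weights; σ_f := 0 when M ≤ 1.

### Daily residual kriging

Residuals are formed on the log scale from the out-of-bag ensemble mean
(in-sample residuals would be optimistically small) and kriged on the
log scale, then added to μ_f before back-transform.  Each day is fitted
independently — a deliberate simplification that avoids assuming
temporal stationarity of the residual field.

Two fitting routes exist:

* **WLS on the binned empirical variogram** (`fit_variogram`): bins up
  to a cutoff of one third of the maximum inter-station distance
  (12 bins, ≥5 pairs each, semivariances plotted at mean pair distance),
  weights N_j/h_j², multi-start trust-region optimisation with
  non-negativity bounds.  An approximate F-test (α = 0.05) against the
  pure-nugget model guards against structure fitted to bin noise.
* **Profiled Gaussian REML on the residual values**
  (`fit_variogram_ml`, the default for daily fitting): the constant mean
  and overall variance are profiled out analytically, leaving a 2-D
  search over (nugget ratio, range), multi-started deterministically.  A
  likelihood-ratio test against the iid model (χ²₂, α = 0.05) collapses
  days without credible spatial structure to pure nugget.  REML was
  chosen after measuring that binned WLS estimates the exponential range
  with 45–100% median relative error at 96 stations while REML achieves
  ≈25–30% — close to the information bound for a single day's
  realization at this network size; range estimation at n = 96 is
  intrinsically noisy and users should read daily range series as
  seasonal patterns, not per-day truth.

Family selection runs leave-one-station-out kriging per candidate family
(spherical, circular, exponential, Gaussian, linear) and keeps the
lowest LOOCV RMSE; because the bounded families produce nearly identical
kriging predictions, a competitor replaces the exponential default only
when it wins the paired squared-error comparison at a
Bonferroni-corrected 5% level — otherwise the difference is treated as a
tie in favour of the exponential family.

Ordinary kriging solves the augmented (n+1)×(n+1) system with the
Σλ = 1 constraint directly (all ≤96 stations in every neighbourhood; no
moving window at this n).  Exactly duplicated station coordinates are
averaged first.  γ(0) = 0 exactly, so the predictor is exact at data
points when the nugget vanishes.  Days with fewer than 10 reporting
stations are flagged and contribute a zero residual surface.  For the
exponential family both a0 and the effective range 3·a0 are reported,
since "range" conventions differ between tools.  Daily surfaces can be
transferred to other years by day-of-year lookup; this assumes
between-year stability of the residual variograms and is flagged as an
extrapolation.  Block means are discretised averages of the
(bilinearly interpolated) point surface over a polygon.

## Validation scenarios

Six scenarios span engine × PM₁₀ × kriging: (1) single GAM, (2) single
GAM + PM₁₀, (3) bagging, (4) bagging + kriging, (5) bagging + PM₁₀,
(6) bagging + PM₁₀ + kriging.  Single-model scenarios are scored by
repeated k-fold CV (default 10 × 10-fold, record-level fold assignment;
a leave-stations-out mode exists for sterner spatial validation but is
not the default).  Bagging scenarios are scored out-of-bag.  In kriging
scenarios the residual at a held-out station uses only the *other*
stations' residuals that day (leave-one-station-out), so the kriging
gain is not an artefact of self-interpolation.  Metrics (R² = 1 −
SSE/SST; RMSE) are computed on the concentration scale after
back-transform.

## Synthetic data

The generator emulates the study conditions: 96 stations × 365 days in a
350 × 250 km domain, stations placed in ~16 tight urban clusters with a
rural background (mirroring a national network concentrated in cities);
log PM₂.₅ = winter-high cosine (amplitude 0.4, per-station loadings
±10%) + harmonic (0.1) + smooth covariate effects (AOT, temperature —
deliberately non-monotone, wind speed via both components, road length,
forest fraction) + a daily Gaussian random field + iid noise (SD 0.05).
The field is drawn by Cholesky factorisation from an exponential
variogram whose parameters follow a sinusoidal winter/summer schedule:
nugget 0.005/0.0025, partial sill 0.12/0.06, range parameter a0
45/22 km.  The 2:1 range schedule makes the day-median effective range
3·a0 ≈ 93 km, consistent with published provincial residual-range
summaries; the structured field carries ≈40% of the log variance, so
kriging has something substantial to recover.  PM₁₀ is PM₂.₅ divided by
a ratio drawn per record from a truncated normal on (0.2, 0.95) whose
location follows a seasonal + smooth day-level path around 0.57
(overall SD ≈ 0.10); the day-level component is shared across stations,
which is why kriging still helps slightly even when PM₁₀ is a predictor.
Missingness is applied completely at random at 4%.

What the synthetic experiments show: the pipeline recovers planted
smooth effects, the seasonal basis, the variogram schedule's seasonal
pattern, and the scenario ordering (kriging gain ≥ 0.1 without PM₁₀).
What they do not show: performance under real covariate error,
spatially structured missingness, network expansion/closure, emission
trends, or covariates with realistic spatial texture — the generator's
covariates are statistically convenient, not physically simulated.

## Numerical conventions and edge cases

* Seeds: every stochastic routine takes an explicit seed or Generator;
  equal seeds give bit-identical outputs.
* Daily means require ≥75% hourly coverage, else the day is missing.
* Non-positive concentrations are rejected at panel construction with
  the offending station/day named.
* All distances are planar metres under a local equirectangular
  projection centred on the network (adequate below ~0.5% distortion at
  provincial extent).
* Bootstrap resamples that produce a degenerate design are redrawn (≤10
  times); rows never out-of-bag fall back to the full ensemble mean.
* Kriging variances are clipped at zero against roundoff; singular
  kriging systems raise after duplicate-averaging.
* The day index is 1-based day-of-year; daily means use the configured
  local time zone.

## Known limitations

* Per-day range estimates at 96 stations carry ~25–30% median relative
  error even with REML — an information limit, not an implementation
  one.
* The ensemble SD measures between-member spread, not full predictive
  uncertainty; it omits the residual-kriging variance.
* Record-level CV is optimistic for mapping to unmonitored locations;
  use the leave-stations-out mode for that question.
* Transfer of residual surfaces across years by day-of-year lookup is an
  assumption, flagged but not validated here.
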