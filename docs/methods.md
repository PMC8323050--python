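# Methods

## Data model and timeline

A measurement is one `(subject, group, analyte, day, clock time, value)`
record; a subject × analyte series under the default schedule has 14
scheduled slots (seven clock times × two consecutive days). Analysis runs on
**elapsed hours** since the day-1 08:00 anchor. The two night samples (01:00,
05:00) of a sampling day are taken after midnight, i.e. on the following
calendar day, so day-1 slots map to elapsed {0, 3, 6, 11, 14, 17, 21} and
day-2 slots to the same + 24. This convention is an inference from the
two-consecutive-day design (source protocols typically timestamp night
samples by sampling day only); it matters because it is the only monotone
axis on which the night slopes and the cosinor fit are well defined, and it
is applied uniformly by every module. Missing values are absent or empty
cells, never sentinel numbers: means, slopes and matched differences skip
them rather than absorb them.

## Cosinor fitting

The model is the standard single-component cosinor
Y(t) = M + A·cos(2π(t − φ)/τ). With the wavelength fixed (τ = 24 h for all
primary fits) the model is linear in (M, a, b) where a, b multiply cos ωt
and sin ωt; the closed-form fit is OLS followed by A = √(a² + b²),
φ = atan2(b, a)/ω, and the reported acrophase is the **clock time of the
curve maximum** in [0, 24). R² = 1 − SS_res/SS_tot. The sine
parameterization (conventional for cortisol in some analyses) peaks a
quarter period after its phase parameter and canonicalizes to the identical
(M, A, peak time); all reporting is canonical so the two hormones are
directly comparable.

Numerical choices:

- **Degenerate amplitude**: when A ≤ 1e-8·max(|M|, 1) the acrophase is
  reported as NaN with an `acrophase_undefined` flag (and excluded from
  circular analysis) rather than an arbitrary angle. A constant series also
  flags `r2_undefined`; the SST threshold is a rounding-noise floor
  (n·(1e-12·max|y|)²), since float arithmetic never yields exactly zero SST.
- **Iterative fixed-period fit** (`fit_nonlinear("fixed24")`): a
  Levenberg–Marquardt refinement over (M, A, peak), initialized from the
  closed form. It exists as an independent route to the same optimum and is
  verified against the closed form; the closed form is the default.
- **Free-period fit** (`fit_nonlinear("free_bounded")`): the period is the
  only nonlinear parameter, so it is profiled out by variable projection —
  SSE(τ) with the linear parameters solved in closed form at each τ,
  minimized over τ ∈ [20, 28] h by a 33-point grid (always including 24)
  plus bounded scalar refinement (xatol 1e-8). This is globally robust in
  the linear parameters, guarantees SSE ≤ the fixed-24 SSE, and is fast
  enough for thousands of replicate fits. A period within 1e-4 h of a bound
  is snapped to the bound and flagged `period_at_bound`. The bounds are
  configurable; [20, 28] h is a deliberate default wide enough for human
  circadian estimates from 14 points while excluding aliased optima.
- Fixed-period features (acrophase, peak, mesor, R²) always come from the
  fixed-24 fit; the free-period fit contributes **only** the period feature.
  This keeps a single well-identified phase definition while still reporting
  a per-subject period estimate.
- Group-level display curves are fitted to the pointwise group-mean profile
  by default (a pooled-individual option exists) — the choice affects only
  plots, never the per-subject statistics.

## The 12-feature ledger

Per subject × analyte: free period; acrophase; fitted peak (M + A); fitted
mesor; 24-h average (mean of all present values across both days, the
doubly-sampled 08:00 slots counted as ordinary samples); anchored maximum —
the *measured* value at the analyte's expected-peak slot on day 2 (cortisol
08:00, melatonin 05:00), distinct from the empirical maximum, which enters
only the range (max − min over all present samples); two-day difference —
the **mean** of |day1 − day2| over clock times present on both days (a sum
variant is available behind a flag; the mean is robust to missingness);
and four linear slopes. Daytime slopes regress the 08:00/11:00/14:00 values
of each day on elapsed time. Night-slope triplets are analyte-specific:
cortisol 01:00 → 05:00 → next-morning 08:00 (elapsed {17, 21, 24} for night
1), melatonin 22:00 → 01:00 → 05:00 (elapsed {14, 17, 21}); night 2 adds
24 h. Under the standard schedule the cortisol night-2 triplet's third point
(a day-3 08:00) was never sampled, so that slope is a two-point slope and is
flagged `slope_night2_degraded`. Any triplet with < 2 present points yields
a missing slope; exactly 2 points yields the two-point slope with a
`*_degraded` flag.

## Circular statistics

Peak clock times map to angles by θ = 2π·t/24 (midnight at angle 0). The
mean resultant vector of a group gives the average peak time (direction) and
phase agreement (length R̄ ∈ [0, 1]); R̄ numerically 0 (antipodal
cancellation) leaves the mean direction undefined and flagged. The Rayleigh
uniformity test uses z = nR̄² with the standard small-sample p
approximation. The Watson–Williams test of equal mean directions uses

F = K·(N − k)(ΣR_i − R) / ((k − 1)(N − ΣR_i)),  K = 1 + 3/(8κ̂),

with per-group unnormalized resultants R_i, pooled resultant R, and κ̂
estimated from the within-group mean resultant length ΣR_i/N by the
three-regime maximum-likelihood approximation (regime boundaries 0.53 and
0.85). The test assumes roughly von Mises samples with common, reasonably
high concentration; κ̂ < 2 sets an `assumption_warning`. Zero within-group
dispersion (every angle identical) raises a degenerate-dispersion error
rather than returning an infinite F. Optional weights (e.g. per-subject fit
R²) affect only mean-vector summaries and plots, never the test, whose
theory assumes unweighted samples.

## Group comparison

Exclusion: a subject × analyte profile with **more than four** missing
scheduled slots is dropped, per analyte (a subject can be retained for one
hormone and excluded for the other). Features are compared pairwise
(control–depression and control–recovery by default) with a two-sided
pooled-variance Student's t at α = .05; Welch is available and recommended
when variances differ visibly. No multiple-testing correction is applied by
default — mirroring the analysis style this pipeline reproduces, which tests
12 features per hormone at raw α — and a Benjamini–Hochberg option
(per analyte × pairing family) is provided for confirmatory use. Groups with
fewer than two usable values yield rows marked not computable instead of a
test. Acrophase is tested both linearly (t on clock values) and circularly
(Watson–Williams); the linear route is fragile when a group's acrophases
straddle midnight — wrapped values inflate the linear variance — so the
circular result is the statistically meaningful one near the 24 h/0 h
boundary, and both are reported side by side.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes: per
subject a true cosinor (mesor, amplitude, acrophase, period) drawn from its
group's distribution — normal mesor and amplitude truncated at zero, with
amplitude additionally capped at the mesor so true concentration curves are
nonnegative; wrapped-normal acrophase; period fixed at 24 h by default
(nonzero period SD is configurable but breaks exact noiseless recovery by a
fixed-24 fit, so it is off by default) — observed through multiplicative
Gaussian noise value = curve·(1 + ε), ε ~ N(0, CV), truncated at zero, with
independent per-slot missingness. Multiplicative noise is used because assay
precision is published as coefficients of variation and hormone levels span
an order of magnitude across the day.

Defaults encode the emulated study conditions: group sizes cortisol
12/10/4 and melatonin 12/8/3 (control/depression/recovery); control cortisol
acrophase 08:00 and control melatonin acrophase 03:50, depression melatonin
advanced to 01:30 (≈2.3 h) and depression cortisol amplitude damped
(2.2 vs 3.5); assay CVs 6.1% (cortisol) and 10.8% (melatonin); 1 h
between-subject circular SD of acrophase (chosen to give the tight control
phase clusters typical of such cohorts); 5% missingness. Mesor/amplitude
scales (cortisol M 5.0 ± 0.6, A 3.5 ± 0.5 ng/ml; melatonin M 12 ± 2,
A 8 ± 1.5 pg/ml) are order-of-magnitude realistic choices for salivary
assays — the emulated study printed no numeric values for them, so they are
generator conventions, not estimates. Truth and noise use independent
seeded substreams, so the same seed draws the same subjects at any noise
setting, and a truth table accompanies every cohort for recovery scoring.

What the generator does **not** model: secretory pulsatility, the strongly
non-sinusoidal shape of real melatonin (near-zero daytime, sharp nocturnal
rise), light responses, or within-subject day-to-day phase drift. Passing
tests therefore demonstrate that the pipeline recovers what it assumes —
cosinor structure observed with assay noise — not that real hormone profiles
are cosinor-shaped.

## Simulation studies built into tests and the acceptance script

Replicate counts are chosen to give tight Monte-Carlo error at desk scale:
200 profiles for fitting-route agreement; 500 subjects per analyte for
noisy acrophase recovery (median |error| ≈ 0.10 h cortisol, ≈ 0.17 h
melatonin at the assay CVs); 100 cohorts at study group sizes (12 vs 8) for
phase-advance detection; 1,000 (tests) or 500 (script) null cohorts for
type-I calibration, where 5% rejection has a binomial SE of ~0.7% (1,000) to
~1% (500). Phase-advance recovery is scored against the realized per-cohort
truth (the circular mean of the drawn true acrophases), isolating pipeline
error from between-subject sampling variation, which at n = 12 vs 8 with
1 h circular SD contributes ~0.5 h SD to the group difference on its own.

## Known limitations

- The t test on acrophase treats a circular quantity linearly; it is kept
  because it is the conventional analysis being reproduced, but inference
  near midnight should rely on the Watson–Williams result.
- A 14-point, 2-cycle design weakly identifies a free period; the period
  feature has wide sampling variability and the [20, 28] h bounds are part
  of its definition.
- The Watson–Williams correction is an approximation that degrades at low
  concentration (flagged at κ̂ < 2) and assumes equal group concentrations.
- Exclusion is a hard threshold on missing-slot counts; no imputation is
  attempted anywhere.
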