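# diurnal

Cosinor and circular-statistics analysis of two-day salivary **cortisol** and
**melatonin** profiles, for chronobiology and mood-disorder studies that
assess circadian rhythmicity from sparse timed saliva sampling.

The package targets the common clinical design in which saliva is collected
at seven clock times — 08:00, 11:00, 14:00, 19:00, 22:00, 01:00 and 05:00 —
on two consecutive days (14 scheduled samples per subject and hormone), and
groups of subjects (healthy controls, patients in a depressive episode,
patients in recovery) are compared on the parameters of their daily rhythms.

## What it computes

**Cosinor model.** Each subject × hormone series is fitted with the
single-component cosinor

```
Y(t) = M + A · cos( 2π (t − φ) / τ )
```

with mesor *M* (rhythm-adjusted mean), amplitude *A* ≥ 0, acrophase *φ*
(reported as the clock time of the curve maximum) and wavelength *τ* fixed at
24 h, plus the goodness of fit *R²*. With *τ* fixed the least-squares optimum
is available in closed form (OLS on cos ωt and sin ωt); an iterative fit and
a bounded free-period variant (*τ* ∈ [20, 28] h, for the period parameter
only) are also provided. An equivalent sine parameterization is supported and
canonicalized to the same peak-clock-time form.

**Feature ledger.** Twelve per-subject rhythm parameters: free period,
acrophase, fitted peak, fitted mesor, 24-h average, anchored maximum
(cortisol: day-2 08:00; melatonin: day-2 05:00), range, two-day difference
(mean |day1 − day2| at matched clock times), and daytime/night linear slopes
for both days, always regressed on elapsed time so the night samples that
cross midnight stay monotone.

**Circular statistics.** Acrophases are mapped to angles on a 24-h circle
(θ = 2π·t/24); groups are summarized by mean resultant vectors (direction =
average peak time, length = phase agreement), tested for uniformity with the
Rayleigh test (z = nR̄²), and compared with the **Watson–Williams F test**
with the standard 1 + 3/(8κ̂) concentration correction.

**Group comparison.** Profiles missing more than four of the 14 scheduled
samples are excluded per hormone; every feature is compared between group
pairs with a two-sided Student's t test (pooled by default, Welch by flag) at
α = .05, with optional Benjamini–Hochberg correction; the acrophase rows also
report the circular Watson–Williams result.

**Synthetic cohorts.** Because studies of this design rarely deposit raw
measurements, a seeded generator produces cohorts with the same statistical
structure — cosinor-shaped truths with between-subject variation, wrapped
normal acrophases, multiplicative assay noise at the published ELISA CVs
(6.1% cortisol, 10.8% melatonin) and sporadic missingness — together with a
ground-truth table, so every stage of the pipeline is verifiable end to end.

## Worked example

```python
from diurnal import simulate, pipeline
from diurnal.cosinor import Cosinor

profiles, truth = simulate.simulate_cohort(simulate.default_config(seed=7))
res = pipeline.analyze(profiles)

print(Cosinor.from_profile(profiles[26]).fit().summary())
```

```
Cosinor fit
===========
n used                    14
form                  cosine
period (h)           24.0000
mesor                14.4361
amplitude            12.9427
acrophase (clock)     3.6118
fitted peak          27.3788
R-squared             0.9771
SSE                   23.559
```

This control subject's melatonin rhythm peaks at a fitted 27.4 pg/ml around
03:37, with the cosine explaining 97.7% of the variance. At the cohort level:

```python
print(res.circular_summary)
#   analyte      group  n  mean_clock  resultant_length  rayleigh_z  rayleigh_p
#  melatonin    control 12       3.582             0.995      11.878       0.000
#  melatonin depression  8       1.723             0.976       7.615       0.000
#  ...
adv = pipeline.acrophase_group_difference(res.feature_table,
                                          "melatonin", "control", "depression")
print(round(adv, 2))   # 1.86
```

The depression group's melatonin peak is estimated 1.86 h earlier than the
controls' (this seeded cohort was generated with a ~2.3 h true advance). The
comparison table reports both tests for acrophase; in this cohort the
Watson–Williams test rejects decisively (F = 39.4, p ≈ 6e-6) while the linear
t test does not (p = .61) because one depression acrophase wraps past
midnight — exactly why the circular route is reported alongside the t test.

The same analysis runs from the shell:

```
diurnal simulate --out sim --seed 7
diurnal analyze sim/profiles.csv --out analysis
diurnal report analysis
```

which writes `fits.csv`, `features.csv`, `comparisons.csv`, `circular.csv`,
`exclusions.csv`, a run manifest, and profile/phase-dial figures.

## Layout

- `diurnal.data` — domain types, schedule/timeline conventions, CSV I/O
- `diurnal.cosinor` — `Cosinor` model / `CosinorResults` (fit, predict, summary)
- `diurnal.features` — the 12-parameter ledger
- `diurnal.circular` — phase angles, mean vectors, Rayleigh, Watson–Williams
- `diurnal.compare` — exclusion rule, t tests, comparison tables
- `diurnal.simulate` — synthetic cohort generator with ground truth
- `diurnal.pipeline` — end-to-end analysis; `diurnal.cli` — shell commands

See `docs/methods.md` for the statistical methods, defaults and limitations.
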