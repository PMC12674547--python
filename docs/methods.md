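# Methods

## Model

The package models a subject's daily performance proxy `P` as adaptation
minus fatigue, each component the sum of a decaying exponential in the
calendar day index `t`, an instantaneous gain in that day's normalized
external load `w`, and an integration constant:

```
A(t, w) = a·e^(−τₐ t) + Kₐ·w + C₁
F(t, w) = f·e^(−τ_f t) + K_f·w + C₂
P(t, w) = A − F
```

Assumptions, stated explicitly:

1. No overtraining: adaptation and fatigue respond beneficially to load and
   fade monotonically; paradoxical autonomic responses are out of scope.
2. The exponentials decay in a single global day index (first session at
   `t = 1`), not as a convolution over past training impulses. This is a
   deliberate modelling convention: the closed form treats the 12-week block
   as one impulse-response episode. The classic multi-impulse convolution
   variant is intentionally not implemented.
3. Writing the homogeneous decay solution with a free amplitude and an
   additive constant (`a·e^(−τt) + C`) is itself a convention — the pure
   exponential-decay differential equation has no additive constant in its
   general solution. The constants are retained as adjustable parameters
   because they absorb each indicator's baseline level, and the final
   eight-parameter form is implemented verbatim.

### Identifiability

`P` depends on `(Kₐ, K_f)` and `(C₁, C₂)` only through ΔK = Kₐ − K_f and
ΔC = C₁ − C₂: adding a common constant to either pair changes nothing.
Estimation therefore works in the six-dimensional identifiable space
`(a, τₐ, f, τ_f, ΔK, ΔC)` and reports eight coefficients under the
convention K_f = 0, C₂ = 0, flagged `canonical` in every serialized fit.
The two exponential terms are also label-exchangeable (swapping them with
negated amplitudes preserves every prediction); `canonicalize` resolves
this by requiring τ_f ≥ τₐ — fatigue decays at least as fast as
adaptation, the physiologically standard ordering. On an exact τ tie the
sign-preserving swap cannot change the amplitude ordering, so tied inputs
are returned unchanged.

## Load indicators

* **External load** `W`: rectangular 1 s sum of ergometer speed ×
  resistance over the session. Data are 1 Hz samples, so the rectangular
  rule is the natural integral; a trapezoid differs negligibly and is not
  offered.
* **ΔHRR1** (bpm): peak heart rate of the final training minute minus the
  mean heart rate over post-exercise seconds 1–60.
* **HRr%**: `100·(HR_stage1 − HRR1)/HR_stage1`, with HR_stage1 the mean
  over post-exercise seconds 1–15. "Average heart rate 15 seconds after
  training" is read as a window mean, not the instantaneous value at
  second 15; the windows are the natural wearable-summary reading.
* **TL_HRV**: `(Pre5 − Post5)/(Post30 − Post5)` on raw RMSSD values of the
  three resting 5-minute R-R windows. The 0.1–1 normalization is applied to
  the resulting indicator series, not to the RMSSD inputs. A day with
  Post30 = Post5 has an undefined ratio and is flagged and dropped before
  splitting, with a logged count; Post30 < Post5 (negative ratio — HRV
  still suppressed at 30 min) is passed through unaltered rather than
  re-oriented.

Normalization maps each per-subject series affinely onto [0.1, 1]
(min → 0.1, max → 1.0). The 0.1 floor guarantees the output ratio
`P = W_norm / I_norm` is bounded in [0.1, 10] and can never divide by
zero. The scale is computed over the subject's full series — matching the
normalize-then-split order of the workflow this package implements — which
leaks the test-day extrema into the scale; a leakage-free mode
(`learning_fraction=0.8` in `enrich_day_table`, `--learning-only-norm` in
the CLI) computes the affine map on learning days only, in which case test
values may fall outside [0.1, 1].

## Estimation

Per subject and indicator, the first `floor(0.8·n)` chronologically ordered
days form the learning set (floor keeps the test set non-empty at every n);
the rest are held out. `FitnessFatigueRegressor` minimises the sum of
squared errors with scipy's trust-region-reflective bounded least-squares
solver, restarted from 32 seeded draws — decay rates log-uniform over
[1e−4, 5] per day, linear coefficients standard normal — because the
two-exponential landscape is multimodal. Each start draws from its own
`SeedSequence` child, so a longer multistart schedule extends a shorter one
and the returned SSE is non-increasing in the number of starts. Bounds
(τ ∈ [1e−4, 5]/day, |a|, |f|, |ΔK|, |ΔC| ≤ 100) are wide pragmatic boxes,
exposed as constructor arguments; the τ lower bound keeps the exponentials
finite, the upper bound (τ = 5/day ≈ 5-hour half-life) is faster than any
plausible training response. The fitting floor is 10 learning observations
(configurable). The baseline `P = ΔK·w` has the closed-form no-intercept
solution ΔK = Σ(P·w)/Σ(w²); because it is nested in the optimized model,
the optimized SSE can never exceed it — this is asserted in tests against
both a brute-force 6-D grid oracle and the closed form.

Learning-set R² is `1 − SSE/Σ(P − mean P)²`; it can be negative for fits
worse than the mean and is NaN (flagged) on constant observations.

## Evaluation battery

Held-out predictions from frozen parameters are scored with RMSE and MAPE.
Temporal dependence of error is tested with a Spearman rank correlation
between prediction horizon (days since the last learning session) and
absolute percentage error; the two-sided p-value is exact by enumerating
all permutations of the error ranks for n ≤ 8 test days and uses the
t approximation beyond. Per-subject metric pairs (optimized − original)
are tested with Shapiro–Wilk normality gating at α = 0.05: normal
differences go to a two-sided paired t-test, otherwise a Wilcoxon
signed-rank test (zeros discarded, ties average-ranked, exact where
attainable for n ≤ 15, normal approximation otherwise). The Bonferroni
family defaults to m = 3 — the three internal-load indicators compared per
metric — and is config-exposed; corrected p = min(1, m·p).

## Synthetic cohort generator

The generator emulates the structure of a 13-subject, 12-week
medium-intensity continuous-cycling cohort: 3 planned sessions per week
(days 1/3/5 of each week), 30-minute sessions, final-minute heart rate at
85 % of the subject's maximum, attendance defaulting to 88.5 % (misses
removed uniformly at random, schedules re-anchored so the first attended
session is day 1), giving 28–42 attended sessions over a 71–82 day span.
Ground-truth parameters are drawn per subject from ranges consistent with
the impulse-response training literature: adaptation decays over weeks
(τₐ ∈ [0.02, 0.05]/day, i.e. 20–50-day time constants), fatigue over days
(τ_f ∈ [0.10, 0.40]/day), amplitudes a, f ∈ [0.8, 1.5], ΔK ∈ [0.3, 0.8],
ΔC ∈ [0.2, 0.6] — magnitudes that keep the performance proxy in the
plausible range of a normalized-load ratio.

Noise is deliberately minimal because each term has a testable closed-form
consequence: additive Gaussian noise (default sd 0.05) on the day-level
performance proxy, so the zero-noise channel equals the model exactly; and
iid Gaussian jitter on R-R intervals, whose sd is set to
`target RMSSD / √2` because the RMSSD of iid jitter on a constant-rate
window has expectation `sd·√2`. Post-exercise heart rate recovers as a
single exponential toward resting rate with a per-session time constant
drawn from [40, 80] s — the day-to-day variation the HRR indicators are
meant to capture. What the generator does *not* emulate: HRV
nonstationarity and circadian structure, ectopic beats and measurement
artefacts, HR drift within a steady-state session, attendance patterns with
structure (e.g. end-of-term clustering), and any feedback from fatigue
state onto attendance or load. Passing tests on this generator therefore
demonstrate correctness of the formulas and estimation machinery under the
stated noise model, not robustness to real wearable-data pathologies.

## Numerical choices

* Floats in JSON reports are rounded to 12 significant digits so identical
  seeds give byte-identical files.
* `least_squares` runs with `max_nfev = 5000`; starts that fail to
  converge are dropped, and only if every start fails is an estimation
  error raised with diagnostics.
* Exact Spearman enumeration caps at n = 8 (8! = 40 320 permutations);
  the t approximation takes over beyond.
* Day indexing is 1-based calendar days from the first attended session,
  stated in every file header.

## Identifiability limits and known limitations

A recovery study (13 subjects × 36 sessions, noise sd 0.05 — run by
`scripts/acceptance.py`) recovers ΔK to well under 10 % median relative
error and both decay rates to roughly 10–25 %. ΔC is the least
identifiable quantity: over an 84-day window a slow adaptation exponential
is nearly collinear with a constant, and the Cramér–Rao bound at the
generating parameters puts the *best attainable* median relative error on
ΔC near 15 % at this noise level — the fitted errors sit at that limit,
so the residual error is information-theoretic, not an optimizer defect.
Practical consequences: fitted C₁ (= ΔC) values should be read with wide
uncertainty on 12-week datasets, and comparisons between subjects should
rely on ΔK and the decay rates.

Other limitations: the per-subject normalization makes fitted parameters
scale-dependent (they describe the subject's own 0.1–1 range, not absolute
load); single chronological split, no cross-validation; no pooling across
subjects (each fit is independent, as the per-subject workflow intends);
and the reported 8-parameter vectors are one representative of an
equivalence class — only the identifiable summary is comparable across
software.
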