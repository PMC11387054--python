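# Methods

`wakeflight` reconstructs, as a tested pipeline, the analysis chain used
to ask whether birds flying *in the wake* of a flockmate — in the upwash
shed outboard of the leading bird's wingtips — spend less energy than
birds flying outside it.  The pipeline consumes per-bird trajectories
(5 Hz, metric east/north/up), tri-axial body acceleration (20 Hz, g)
and heart rate (bpm), and produces mixed-effects estimates of the
in-wake effect on three energy proxies: vectorial dynamic body
acceleration (VeDBA), heart rate, and effective wingbeat frequency.
Because the original tracking data are not redistributable, the package
ships a synthetic flock generator with known injected effect sizes;
every downstream stage is validated by recovering them.

## Wake classification

The in-wake region behind a bird has gradual boundaries, so membership
is fuzzy: three trapezoidal functions over the follower's offset in the
*leading candidate's* flight frame — lateral distance from the midline
`|dy|`, longitudinal distance behind `-dx`, vertical offset `dz` —
combined with a minimum (single-rule Mamdani system).  A follower's
degree is the maximum over all frontal candidates (ahead of the
follower along its own flight direction, within 20 m); the crisp state
is cut at 0.5 and the arg-max candidate named leader (ties by distance,
then id).

The *pre-defined* parameter set is motivated by fixed-wing wake theory:
the wingtip vortex of a wingspan-`b` wing sits near `pi*b/8 ≈ 0.59 m`
from the midline for `b = 1.5 m`, with upwash outboard of it.  Defaults:
lateral trapezoid (0.45, 0.6, 1.1, 1.4) m on `|dy|`; longitudinal
(0.3, 0.8, 6.0, 10.0) m behind; vertical (−1.0, −0.5, 0.5, 1.0) m.
These are declared stand-ins — every breakpoint is configurable and no
test depends on the exact values.  The *re-defined* set is re-derived
from the data: the plateau of each trapezoid is the bounding box of the
25% highest-density region of the mirrored nearest-frontal co-planar
offsets, the ramps extend to the 50% region's box.

The flight frame uses the leader's *horizontal* velocity (forward),
the world up axis, and their horizontal complement (right), so `dz`
stays a true altitude difference.  Velocity is a central difference
over 1 s (5 fixes), which stabilises the frame against 5 Hz jitter;
the ground-truth states of the simulator are computed with the same
stencil so that truth and classification share one kinematic
convention.

## Signal proxies

* **VeDBA** — Euclidean norm of the three axes after removing a centred
  running-mean static component.  The exported function defaults to a
  2 s window (far above the 0.27 s wingbeat period); the alignment
  stage uses 4 s, because the mean of a truncated sinusoid over a
  window of length `T` leaves a residual of order `2A/(2πfT)` that
  leaks flapping signal into glide-phase VeDBA — at 4 s the leak is
  ~1.5% of the glide-phase signal rather than ~6%.
* **Flap/glide labels** — moving standard deviation (0.5 s) of the
  mean-removed heave, thresholded at 0.1 g with 2-sample hysteresis.
* **Effective wingbeat frequency** — executed wingbeats per second of
  flight: peaks with prominence ≥ 0.2 g and spacing ≥ 0.15 s (so a
  3.6–3.7 Hz beat is never double-counted), divided by duration.  In
  the pipeline, peaks are detected once on the continuous heave stream
  and assigned to bouts by timestamp; per-segment detection loses the
  edge peak of short bouts and, because in-wake bouts are shorter on
  average, that loss is state-asymmetric and biases the in-wake
  comparison.
* **Flapping frequency** — the periodogram mode of mean-removed heave
  in 1–8 Hz; glide pauses do not move the spectral mode, which is
  exactly why the effective frequency falls below it in intermittent
  flight.

## Cleaning, alignment, bouts

Trimming (default 600 s each end), masking of low-accuracy fixes,
linear interpolation of gaps strictly under 1 s, and optional
thermal exclusion (≥ 360° cumulative heading rotation within 20 s while
climbing ≥ 0.5 m/s — circling climbs; the criterion is this package's
own, as is the stream-offset estimator).  20 Hz quantities are averaged
into each 0.2 s trajectory bin; heart rate is binned or sample-and-held.
The accelerometer/GNSS clock offset is estimated by cross-correlating
the glide envelope with the (sign-flipped) high-passed altitude —
gliding birds sit slightly lower — and a bird is excluded when a
confident correlation peak sits beyond 1 s (the out-of-tolerance peak
must beat the best near-zero-lag correlation by 1.5×; exclusion
requires clear evidence).

Bouts are maximal runs of constant (state, leader) on the 5 Hz clock;
invalid gaps strictly under 1 s are bridged when the same (state,
leader) flanks them — a brief excursion to the other state always
splits, i.e. "gaps" are missing data, not state flips.  Runs under the
minimum duration (2 s default, 5 s alternate) are dropped; contiguous
glide runs over 5 s are masked from all summaries.  Bout-mean heart
rate excludes the first 1 s of each bout (`hr_settle_s`): heart rate
adjusts to a workload change with a lag, so the first moments of a bout
still reflect the previous state; without this exclusion every
bout-level contrast is shrunk toward zero.  A plausibility screen
(bpm outside [100, 700] or sample-to-sample jumps over 150 bpm)
replaces a visual check with explicit rules.

The per-sample VeDBA models use only samples *inside* retained bouts
(transition flicker is not a stable flying position) and only pure
flap or pure glide 0.2 s bins, eroded by one bin at label transitions:
mixed bins would let glide-*rate* differences between the states
masquerade as VeDBA differences (in-wake flight glides more, and glide
VeDBA is ~4× smaller than flapping VeDBA).  The 5 Hz points are thinned
to 1 Hz before fitting — the 4 s VeDBA window makes neighbouring 5 Hz
samples almost entirely redundant, and the thinning keeps the residual
independence assumption more honest.

## Statistical models

**VeDBA.** VeDBA is strongly bimodal by flap/glide, so gliding and
flapping are modelled separately: fixed effect of flying position
(not-in-wake reference); random intercepts for bird, date and
bird-in-date; random slopes of position within each grouping factor,
uncorrelated with the intercepts (the slope indicator is centred within
its grouping factor).  The gliding response is log-transformed
(left-skewed), so its effect back-transforms as `100·(exp(β)−1)`; the
flapping effect is reported as `100·β/intercept`.  Fits are REML via
lme4 (`bobyqa`, 10 000 evaluations) through `Rscript`; the
statsmodels variance-component formulation (all components as variance
components of a single super-group) is the fallback backend and the
cross-check — the two agree on shared data in the test suite.
Intervals for these models are Wald (±1.96 SE): a parametric bootstrap
of a model with six variance components on tens of thousands of rows
is not worth its cost here, and the Wald intervals are validated by
the recovery study.

**Heart rate.** Bout-mean heart rate is right-skewed and is
reverse-score square-root transformed, `x = sqrt(C − hr)` with
`C = 511.2` bpm; the back-transform is `hr = C − x²`, so a *positive*
transformed-scale in-wake contrast means a *decrease* in heart rate.
Fixed effects: position × flap proportion × bout duration (continuous
covariates z-scored) with all two- and three-way interactions — flap
proportion because flapping raises heart rate and differs by state,
duration because of the carry-over lag.  Random: per-bird intercept
and position slope, uncorrelated.  The per-bird effect combines the
fixed slope with the bird's conditional (BLUP) slope and
back-transforms at the bird's own intercept into a percent heart-rate
change.  Per-bird intervals come from a parametric bootstrap that
holds the conditional random effects fixed and redraws residuals
(the conditional analogue of `bootMer(use.u=TRUE)`), so each bird's
interval is centred on its own estimate; percentile 95% bounds,
seeded.  The full-vs-null comparison (dropping every position term,
fixed and random) refits both models by maximum likelihood, since REML
likelihoods are not comparable across fixed-effect structures.
P-values in the fixed-effect table use a residual-df t approximation
and are flagged as such (no Satterthwaite machinery in this backend).

**Wingbeats.** Per bird and position, effective wingbeat frequency is
total detected wingbeats over total bout time in that position
(duration-weighted; an unweighted bout mean over-weights short,
glide-free bouts), and flapping frequency is the duration-weighted mean
of the bout spectral modes.  The position contrast uses a one-sided
paired t-test for effective frequency (directed hypothesis:
not-in-wake > in-wake) and a two-sided paired test for flapping
frequency.  Derived quantities: per-position percent gap
`100·(f_flap − f_eff)/f_flap` and skipped wingbeats per minute
`60·(eWBF_not − eWBF_in)`.

## The synthetic flock

One flight: a front bird follows a slowly meandering heading at
12.2 m/s (44 km/h, OU perturbations); every other bird holds a station
behind its predecessor in that bird's flight frame.  A two-state
Markov switch per bird (exponential dwells, mean 4 s) sets the intent:
*wake-keeping* at (−1.5, 0.85, 0) m (the centre of the membership
plateaus) or *loose following* at (−2.5, 2.0, −0.9) m — laterally
outside the wake support of every bird ahead and below the co-planar
band, consistent with non-wake followers preferring to fly lower.  The
default formation is a same-side echelon so that no bird sits in an
ancestor's wake; a side-alternating ladder is available.  Stations are
reached through a 1 s first-order slew; station-keeping error is a
smoothed Ornstein–Uhlenbeck wander (sd 0.3 m per axis, correlation
5 s, low-passed at 1 s — raw OU noise is nowhere smooth and flickers
any threshold it hovers near, where a real bird's positional error is
differentiable).

**Ground truth is the realized position**: a bird is truly in-wake at
a timestamp iff its offset behind some frontal bird reaches the crisp
membership threshold of the generating fuzzy config (positions exact,
velocities by the same central-difference stencil as the pipeline).
All injected energetic effects key on this realized state — the upwash
affects a bird that is *in* it, not one that intends to be — which is
what makes the injected effects recoverable by a position-based
classifier in the first place.

Heave is a 3.65 Hz oscillation (amplitude 0.5 g, per-bird and per-date
lognormal factors of 5% and 2%) with smaller fore-aft and lateral
harmonics; wingbeats are skipped in runs of 2–8 cycles (uniform),
initiated per cycle with probability 0.0378 (not-in-wake) or 0.0496
(in-wake).  Because a glide run often straddles a state switch, the
state-conditional glide-rate contrast realized in the ground truth is
roughly half the raw probability contrast; the defaults are calibrated
so the *realized* effective-wingbeat-frequency gap is ≈ 0.09 beats/s
with a mean glide fraction near 18% (effective frequency ≈ 3.0,
matching the field system).  During glides the bird sits 0.15 m lower
(0.5 s smoothed), which both mimics glide sink and gives the
stream-offset estimator its signal.  The whole dynamic acceleration is
scaled by `1 − 0.011` when in-wake during flapping and the glide-phase
body jitter (OU, 0.05 g per axis) by `1 + 0.16` when in-wake during
gliding, so mean VeDBA scales by exactly the injected fractions;
additive sensor noise is 5 mg.  GNSS positions get 2 cm noise, with
1.77% of fixes flagged low-accuracy (30 cm noise).

Heart rate (on five of the ten birds; per-bird baselines uniform in
420–440 bpm, date shifts sd 4 bpm, white noise 8 bpm at 5 Hz) follows
`baseline · (1 + effect·s(t)) · (1 + 0.05·(φ − φ̄))`, where `s(t)` is
the true state low-pass filtered with time constant `hr_lag_s` (the
carry-over of cardiac adjustment) and `φ` the smoothed flapping
fraction (flapping raises heart rate).  The in-wake decrement of −2.7%
is designated to two of the five instrumented birds, mirroring the
study's five usable recordings of which two showed a clear effect.
`hr_lag_s` defaults to 0.5 s — two to four heartbeats at 420 bpm.  A
longer constant (e.g. 2 s) against 4 s dwells would shrink every
bout-mean contrast by almost half, making the instantaneous injected
effect unrecoverable from bout means by construction; at 0.5 s with
the 1 s settling exclusion the realized bout-level effect is ≈ 96% of
the instantaneous one, and the validation targets the realized value
(reported alongside the instantaneous one).

What the generator does *not* emulate: aerodynamic wake dynamics, wind
and thermals (a labelled circling segment exists only for the thermal
filter's tests), multi-leader superposed wakes, flap-phase coupling
between birds, and unbalanced missingness beyond random bad fixes.
Passing recovery on this generator therefore shows the pipeline is
consistent and unbiased under its own model of the data — not that the
field estimates are correct.

## Validation study sizes

The standard recovery study is 10 birds × 3 flights × 10 min (90 000
5 Hz bird-samples), with 150–200 bootstrap refits for the heart-rate
per-bird intervals; it runs in well under a minute on one core and is
what both the acceptance tests and `scripts/acceptance.py` execute.
The null configuration zeroes all injected effects and equalises the
glide probabilities; every interval then straddles zero.

## Numerical and degenerate-case choices

* Mixed-model optimisation: lme4 `bobyqa` with 10 000 evaluations;
  statsmodels path tries Powell→L-BFGS, L-BFGS→BFGS and Nelder–Mead
  and keeps the best finite converged restricted likelihood (the
  profiled surface has flat variance-component ridges where a single
  gradient run stalls).  Singular (boundary) fits count as converged.
* Random-effect levels with fewer than two observations are dropped
  with a warning; with a single date the date and bird-in-date
  components are unidentifiable and omitted.
* KDE: Gaussian product kernel, Scott's rule per axis, 64³ grid padded
  by 3 bandwidths, exact (chunked separable) evaluation; region
  volumes are highest-density cell counts × cell volume.  Degenerate
  (zero-variance) clouds raise a bandwidth failure.
* Ties everywhere break deterministically (smaller distance, then
  lower bird id).
* Identical pairs in the paired tests return the boundary p-value
  (0.5 one-sided, 1.0 two-sided) with an undefined t.
* Bouts of exactly the minimum duration are kept (`>=`); a gap of
  exactly 1 s is not bridged (`<`), matching "under 1 s".

## Repository shape

The statistical layer follows the modelling-object convention
(`DbaPositionModel` / `HeartRateModel` with `fit()` returning results
objects that carry estimates, intervals and `summary()`); the
simulation, signal-processing and geometry stages are plain functional
modules — they transform data rather than fit it — orchestrated by
`run_pipeline` and a thin `wakeflight` CLI.

## Known limitations

Satterthwaite degrees of freedom are not computed (residual-df
fallback, flagged in output).  The stream-offset estimator assumes
glide sink is visible in altitude; for a bird that never glides the
offset is unidentifiable and the bird is retained.  The re-defined
fuzzy set inherits the KDE grid resolution (≈ 0.1–0.3 m per cell at
default extents).  Recovery of the gliding VeDBA effect has the widest
intervals because pure-glide samples are ~4% of flight time.
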