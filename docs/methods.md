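# Methods notes

This note records the models implemented in `beartrack`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not demonstrate about real telemetry.

## Data model and covariate matching

Fixes, deployments and hourly station temperatures are plain CSV tables with
UTC ISO-8601 timestamps; all intervals are exact timestamp differences in
hours (duty cycles are specified in hours, so no calendar rounding is ever
applied). Duplicate `(tag_id, time)` rows keep the first occurrence with a
logged warning — a deterministic convention, since transmitters occasionally
deliver the same fix twice.

Temperature is matched to a position by linear interpolation between the
bracketing hourly records of the station nearest (great-circle) to the track
segment's centroid; if the nearest record is more than `max_gap_h` (default
6 h) away the position is flagged covariate-missing and later dropped from
HMM input rather than imputed. Interpolation versus nearest-hour matching is
a genuinely open choice; interpolation was picked because hourly station
series are smooth at the 4-h scale and it removes a ±30 min discretization
artifact. Covariate-missing steps are dropped, not imputed, because no
defensible imputation model for coastal air temperature is simpler than just
omitting the handful of affected steps.

## Filtering sequence

* **Truncation** removes fixes earlier than 72 h after attachment
  (immobilization affects movement); the boundary fix is retained (`>=`).
* **Speed filter**: the McConnell root-mean-square construction — each fix's
  RMS speed against its two preceding and two following retained neighbours —
  with iterative removal of the worst offender until all interior fixes are
  below 40 km h⁻¹. Endpoints are never removed (they lack two-sided
  neighbours). Only the speed test is implemented; the ancillary
  angle/spike tests some filtering packages add are deliberately omitted,
  with a simpler successive-pair mode available behind
  `speed_mode="pairwise"` for sensitivity checks. The loop terminates
  because each iteration removes one fix, and the fixed point makes the
  filter idempotent.
* **Terrestrial selection**: land fixes are kept; a maximal run of marine
  fixes is kept iff it is shorter than 50 fixes *and* bounded by land fixes
  of the same deployment on both sides (the bear returned to land). Leading
  and trailing marine runs are removed. Land status comes from the per-fix
  flag when present, else point-in-polygon against a supplied lon/lat land
  polygon (shapely).
* **Segmentation** splits strictly after gaps > 24 h (a gap of exactly 24 h
  does not split) and discards segments with < 100 fixes, which carry little
  information about state switching; discarded counts are reported so stage
  accounting stays conservative (input = removed + retained everywhere).

## CTCRW regularization

Per planar axis (independent axes, isotropic error — standard practice when
only per-class error radii are available):

    dv = -beta * v dt + sigma dW,   dx = v dt,   z = x + N(0, sd^2)

with the exact discrete-time transition and process covariance of the
integrated Ornstein–Uhlenbeck process. Coordinates are projected to a local
azimuthal-equidistant plane centred on the segment centroid (spherical
closed forms; round-trip error < 1 m within 500 km, verified by property
test). `(beta, sigma)` are maximized on the log scale by Nelder–Mead over
the Kalman likelihood; measurement SDs are fixed per fix.

Default Argos class SDs (km): 3→0.25, 2→0.5, 1→1.5, 0→5, A→8, B→15, GPS
0.02. The Argos system publishes only nominal bounds (class 3 < 250 m,
2 < 500 m, 1 < 1500 m, 0 > 1500 m, A/B unestimable), so these are declared
defaults following the bound structure with conservative values for the
unestimable classes — all config-overridable. A 1 m floor on measurement SD
keeps smoother covariances invertible in noise-free synthetic limits.

The output grid is anchored at the segment's first fix (deterministic and
reproducible; no anchor is canonical) and runs to the last fix — never
extrapolating. Grid points with no observation within 1 h are flagged
`interpolated`. If the optimizer fails for a segment, piecewise-linear
interpolation onto the same grid is used and the segment is flagged in the
report so results stay auditable.

## The behavioural HMM

Two states on the 4-h grid: gamma step lengths parameterized by (mean, sd)
with shape = mean²/sd², rate = mean/sd² (matching how step distributions are
conventionally reported), and von Mises turn angles. Transition
probabilities use a multinomial logit in temperature; three formulations
(intercept-only, + temp, + temp + temp²) give K = 11, 13, 15 free parameters
for two states (2N gamma + 2N von Mises + N(N−1)(1+p) transition + N−1
initial-distribution parameters). The initial distribution is estimated
freely and shared across segments. Each segment is an independent series
under the shared parameters; the first turn of each segment is undefined and
contributes step density only.

Conventions worth stating:

* The transition into step *t* uses the covariate at step *t−1* (the source
  step); the simulator uses the identical convention, and the
  forward/Viterbi recursions are verified against exhaustive path
  enumeration (T ≤ 10, |Δ| < 1e−8) which shares only the convention, not the
  code path.
* Exact zero steps are replaced by half the minimum positive observed step
  before fitting. The three K values above leave no room for zero-inflation
  parameters, so a zero-mass treatment rather than extra structure is the
  consistent reading.
* Viterbi ties break toward the lower state index; after fitting, states are
  relabelled so state 1 has the smaller step mean ("resting") — resolving
  label switching deterministically.
* AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1) with n = the number of step
  observations (alternatives — fixes or segments — are defensible, but steps
  are the likelihood's observational unit).

**Optimization.** Direct maximization of the forward log-likelihood
(numba-compiled scan) over unconstrained transforms: log for positive
parameters, logit for the initial distribution, and the von Mises pair
mapped to the plane point κ·(cos μ, sin μ). The planar angle transform
matters: optimizing (μ, log κ) has a flat ridge as κ→0 where gradients in
log κ vanish and restarts stall at κ ≈ 0; the planar form has a regular
gradient at the origin and eliminated that failure mode. Temperature is
z-scored internally; coefficients are reported on both the standardized and
the raw °C scale (exact polynomial re-expansion). Restarts draw step means
log-uniformly between the 5th and 95th percentiles of observed steps
(ordered), SDs equal to means, angle means from {0, π}, concentrations
log-uniform on [0.1, 5], dwell probabilities uniform on [0.7, 0.99], and
covariate coefficients at 0. A restart counts as converged when L-BFGS-B
reports success or the final projected-gradient inf-norm is below 1e−3 —
finite-difference gradients cannot certify much tighter tolerances reliably.
Fits are deterministic given the seed.

Only N = 2 is fitted: with 4-h fixes and terrestrial data dominated by
resting, additional states are not reliably distinguishable, and the
parameter-count formula is written for general N so the structure documents
the generalization.

## Synthetic studies

The generator mirrors the assumed data-generating process so the pipeline
can be tested closed-loop: hourly temperature = linear seasonal cooling
(default −0.25 °C/day from 10 °C, the early-September-to-December coastal
Hudson Bay regime) + 3 °C diel sinusoid + AR(1) noise (φ = 0.9, innovation
SD 0.8 °C); a two-state latent chain with ~0.95 resting dwell, a 2→1
intercept placing stationary occupancy near 70% resting at season-start
temperature, and a negative temperature coefficient (−0.06 /°C) on
resting→traveling; gamma steps (0.02/0.74 km per 4 h) and von Mises turns
(μ = π, κ = 0.7 resting; μ = 0, κ = 1.5 traveling); class-structured Argos
positional error and the ear-tag class mix 6/14/14/13/18/36% for
3/2/1/0/A/B (printed values sum to 101% from rounding and are normalized);
4-h Argos and 2-h GPS duty cycles with 90% fix success; exponential
detachment times for fur designs (means 22/47/58 days for
pentagon/tribrush/SeaTrkr) and Gaussian battery life for ear tags (121 ± 40
days, 7% detachment), with inactivity-flagged fixes emitted from the
detachment site after a 12-h onset. Latent truth lives on the 4-h
behavioural grid — the scale on which step means are reported — and hourly
true positions are linear interpolations within steps so 2-h duty cycles
can be sampled; positions accumulate on a local plane near the coast and a
latitude half-plane (marine above 58° N) stands in for the coastline, which
is sufficient to exercise the foray rule without GIS data.

The parameter-recovery harness uses the noise-free preset
(`SimConfig.recovery()`): clean 4-h observation, no missed fixes or
failures, bears started inland. This is deliberate — resting steps of
~0.01–0.02 km sit far below even GPS positional noise (~20 m), so recovery
of the resting-state emission parameters is only a well-posed check against
the latent truth when observation noise is off; the noisy default
configuration instead exercises filtering, regularization and bookkeeping.
Passing recovery therefore demonstrates correctness of the inference
machinery at the study's scale, not that emission parameters are
recoverable from heavily degraded Argos data — they are not, which is why
real analyses of this kind lean on GPS segments.

Problem sizes used by the test suite and acceptance script — 10 tracks ×
500 steps for recovery, 20 replicates for sign/model-class recovery, n = 500
for CTCRW recovery — were chosen as the smallest sizes at which Monte-Carlo
error is comfortably inside the stated tolerances.

## Known limitations

* Isotropic per-class Argos error; no error-ellipse model, no multiple
  imputation of tracks.
* One shared parameter set across individuals; no random effects.
* The coastline half-plane and single synthetic station are structural
  stand-ins; real deployments need a land polygon (or per-fix flags) and
  real station series.
* The CTCRW optimizer profiles only (β, σ); measurement SDs are not
  estimated from data.
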