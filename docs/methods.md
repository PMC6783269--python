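# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Bout definitions and kinematics

Input is 40 Hz planar tracking of a single larva: centroid position
(x horizontal, z vertical, mm) and pitch posture (deg, nose-up positive).
Only epochs of at least 2.5 s are analysed.

* **Speed** is the Euclidean centroid displacement across consecutive
  frames divided by the frame interval; a displacement sample is
  attributed to the midpoint of its frame interval.
* **Bouts** are maximal runs of samples with speed > 5 mm/s. Runs whose
  inter-onset interval is shorter than 1/13 s are merged ("faster than
  13 Hz"). We read the merge rule on *onset-to-onset* intervals, consistent
  with the inter-onset definition of instantaneous bout rate; an
  offset-to-onset option is provided (`merge_on="offset"`).
* **Onset/offset** are linear interpolations of the 5 mm/s crossing on the
  rising/falling phases; duration is their difference.
* **Peak speed** is the largest frame-pair displacement in the bout;
  **trajectory** is the direction of that displacement,
  atan2(Δz, Δx) in degrees, mapped to (−180, 180] (up positive). Bouts
  with |trajectory| > 90° (backwards) are excluded and counted.
* **Posture at peak** is taken at the *first* frame of the peak pair; the
  choice between the two frames is otherwise arbitrary, and the first is
  deterministic and onset-weighted.
* **Posture change** is posture(−25 ms) − posture(−75 ms) relative to the
  peak reference frame. At the native 40 Hz these offsets are exact integer
  frame steps (−1 and −3); at other rates posture is interpolated linearly
  in time. Bouts whose −75 ms window precedes the epoch start keep all
  other features but carry `valid_posture_change=False` and are excluded
  from sigmoid fits.
* **Acceleration alignment** uses a ±250 ms window with no smoothing;
  linear acceleration is the first difference of speed, angular
  acceleration the second difference of posture. The window length is a
  package choice (the quantity of interest — the timing of the angular
  peak relative to deceleration onset — is insensitive to it).
* **Light-phase filtering** keeps frames in light intervals within the
  first 24 h, excluding 2 h after each dark→light transition; truncated
  sub-epochs shorter than 2.5 s are dropped.

## Coordination models

Single sigmoid: γ(r) = γ₀ + γ_max/(1 + e^{−k(r−r₀)}). The centre r₀ is
parameterised through the rise position r_rise, the posture change at
which the curve reaches 1/8 of its upper asymptote γ₀ + γ_max. Solving
γ(r_rise) = (γ₀+γ_max)/8 gives

    r₀ = r_rise + (1/k) · ln( 7(γ_max+γ₀) / (γ_max−7γ₀) ),

valid whenever the 1/8 level lies strictly between the asymptotes. This is
derived from the verbal definition of the rise position; printed algebraic
transcriptions of the same relation elsewhere are not sign-consistent with
the fitted parameter values, whereas this form is positive-valued for all
parameter sets used here. Internally the sigmoid is evaluated in the
equivalent r_rise-parameterisation
γ(r) = γ₀ + γ_max/(1 + c·e^{−k(r−r_rise)}), c = 7(γ_max+γ₀)/(γ_max−7γ₀),
which is smooth at k = 0 so that unbounded fits of structureless data
(slope ≈ 0) remain well behaved.

Fit variants (Levenberg–Marquardt, unbounded, fixed initial values
k = 1 deg⁻¹, γ₀ = −0.2°, γ_max = 20°, r_rise = −1°; no multistart):

* `four_param`: all of (k, γ₀, γ_max, r_rise) free;
* `two_param`: k and r_rise free, γ₀ and γ_max fixed at the pooled means
  (−2.97°, 17.02°) — used for decoupled (vestibular-mutant-like) data;
* `one_param`: only k free, all three shape parameters fixed at the pooled
  means (−2.97°, 17.02°, −1.11°) — the developmental comparison.

The **fin-body ratio** is the maximal slope k·γ_max/4 (at r = r₀); the
**fin bias** is slope/(1+slope). R² is 1 − SSE/SST about the sample mean
and may be negative for degenerate fits. The iteration budget is raised
(max_nfev = 5000) because the two-parameter fit is weakly identified when
k → 0 and otherwise trips the default evaluation cap before meeting the
tight tolerances (xtol = ftol = 1e−12).

Double sigmoid (lesion data): γ_p(r) = γ(r) + χ·γ_max/(1 + e^{k(r+r₀)}),
with the nose-up amplitude fixed at 17.02° and initial values χ = 0.5,
k = 1 deg⁻¹, γ₀ = −5°, r_rise = 0°. The nose-up maximal slope is k·γ_max/4
and the nose-down largest-magnitude slope is −χ·k·γ_max/4; both are
reported.

**Bootstrap**: bouts (not residuals) are resampled with replacement;
default 1000 replicates, percentile 2.5/97.5 CIs on the maximal slope and
per-parameter SDs. Replicates that fail to converge are dropped and
counted; more than 10% drops aborts. All resampling is seeded.

## Statistics

* **Chance-level binomial test**: exact tail probability of the subset's
  success count against the overall chance rate, one-sided in the observed
  direction (upper tail above expectation, lower tail below). Sidedness is
  a documented choice — one-sided in the observed direction reproduces the
  magnitudes of all three published worked examples, including the
  lower-tail case — and a two-sided option is provided. Note the published
  chance rates are printed rounded to three decimals, which limits
  recomputation of the far-tail p-values to order-of-magnitude agreement.
* **Conflict proportions**: among bouts with posture change < −1°
  (nose-down) or > +1° (nose-up), the fraction with attack angle above the
  baseline −1.59° (the 1 wpf wild-type sigmoid's vertical location), with
  bootstrap percentile CIs. Empty subsets are reported as undefined.
* **Shallow-climb slope**: Theil–Sen estimate (median of pairwise slopes)
  of attack angle vs posture change restricted to r ∈ [0°, 3°].
* **Equal-count binning**: sort by x and split into contiguous near-equal
  groups, remainder to the leftmost bins; default 20 bins (unspecified
  upstream, configurable).
* **Group tests**: two-way ANOVA (age × clutch) with Tukey HSD follow-up
  on clutch-level means, Kruskal–Wallis fallback for heteroscedastic
  summaries, paired t-tests within clutch, and pooled-bout KS/Spearman —
  via scipy/statsmodels.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
exercised and tested.

Per bout it draws: posture change r ~ N(μ_r, σ_r); attack angle
γ = coupling(r) + N(0, σ_γ); posture at peak ~ N(μ_p, σ_p); peak speed
from a truncated normal (> 6 mm/s so every bout clears the 5 mm/s
detection threshold); and trajectory = posture + attack angle, the
defining identity. Bout peak times are spaced by shifted-exponential
intervals (a 0.55 s floor plus an exponential tail whose mean keeps the
overall rate at the preset's bout rate); the floor keeps rendered bouts
non-overlapping and non-merging except where the merge rule is itself
under test.

Per-age presets use the published marginals (peak speed ≈ 11–14 mm/s,
durations 0.082–0.106 s, posture-change mean ≈ 0.2° and SD ≈ 1.8–2.2°)
and a sigmoid coupling from the *fixed-shape family* (pooled γ₀, γ_max,
r_rise) with age-specific steepness chosen to give maximal slopes 2.76,
2.89, 7.03 and 12.01. Using the fixed-shape family — rather than the
per-age four-parameter fits — follows the empirical finding that only
steepness varies consistently with age, and makes the one-parameter fit a
correctly specified estimator of the generating slope, which is what the
coverage tests quantify.

Two generator scales were calibrated once against published summary
statistics and then frozen:

* attack-angle noise SDs (13.61, 14.21, 13.73, 15.26° per age) reproduce
  the published Spearman correlations of attack angle with posture change
  (0.305, 0.269, 0.379, 0.368);
* baseline posture SDs (17.17, 17.39, 14.62, 13.84°, with mean 3°)
  reproduce the published deviation-from-horizontal values per age.

A consequence worth knowing: matching the rank correlations with this
additive-noise family requires attack-angle marginals wider than the
published ones (≈15° SD rather than ≈6°), because the published
correlations and marginal SDs are not jointly attainable under
sigmoid-plus-independent-noise. The correlations were prioritised since
the fitting and coverage analyses operate on the joint structure.

Condition presets: **otog** (vestibular mutant) copies the 1 wpf marginals
but decouples attack angle from posture change (independent draws with
mean 1.6°, SD 5.2°, matching the published mutant marginal) and inflates
the baseline posture SD by 1.3×; **finless** copies 3 wpf but pins the
attack angle at −8° (small negative, reflecting slight negative buoyancy)
with 2° noise; **lesion** uses the double-sigmoid coupling with the
published χ = 0.63 and k = 1.53 deg⁻¹. The lesion curve's location
parameters are not published; γ₀ = −5° and r_rise = 1.5° (with 4° attack
noise) were chosen so the preset expresses the lesion phenotype —
conflicting actions above the animal's own chance level, nose-up/nose-down
conflict proportions near the published 0.84/0.64, and a small positive
mean attack angle — and then frozen. Sink speed between bouts is 1 mm/s
for all presets (slow passive sinking; not separately published).

The **fin-bias generator** draws a Gaussian steering command s per bout
and splits it: the body receives (1−α)s as a posture change, the fins
receive α·max(s, 0) as an attack angle (fins produce lift only). The
attack : posture ratio therefore never exceeds α/(1−α), attained exactly
on every upward bout, and α = 0 yields identically zero attack angles.
Only this command-split contract is implemented; the full generative cost
model behind it is out of scope.

### Rendering

`render_epoch` turns a bout table into frames: each bout is a half-sine
speed bump whose base width is set so the time above 5 mm/s equals the
bout's nominal duration (half-sines have closed-form threshold crossings,
which the segmentation tests exploit). Peak times are snapped to
frame-interval midpoints so the maximal frame-pair displacement falls on a
known pair and features are exactly recoverable. Heading is fixed at the
bout trajectory during the bump. Posture ramps linearly into the bout at
(posture change)/50 ms, ending by default at the first frame of the peak
pair — so the −75/−25 ms window measures exactly the commanded change —
and drifts linearly between bouts; the ramp end is configurable (e.g.
62.5 ms before peak) to emulate steering that finishes before thrust ends.
Between bouts the centroid sinks straight down at the preset sink speed.

### What the generator does and does not emulate

It reproduces: discrete ~1/s bouts with realistic speeds and durations,
Gaussian posture changes, age- and condition-specific coupling of attack
angle to posture change with the published rank correlations, inter-bout
sinking, and exact frame-level recoverability. It does **not** emulate:
tracking noise or dropped frames, within-bout posture oscillation, tail
kinematics or hydrodynamics, multiple larvae per arena, non-stationary
behavioral state, or realistic attack-angle marginal widths (see above).
Passing tests therefore demonstrate correctness of the *analysis* under
known generative structure, not robustness to acquisition artifacts.

## Problem sizes

Coverage tests use 3000 bouts × 50 seeds per age preset with 200 bootstrap
replicates (the minimum allowed), the round-trip check uses 500 rendered
bouts, and oracle equivalences use 10³ random binomial cases at n ≤ 25;
these sizes make the full suite complete in a few minutes on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The analysis assumes uniform frame timing (1% tolerance) and a single
  larva per epoch; no particle tracking or identity management.
* Percentile bootstrap CIs are first-order; no BCa correction.
* The one-parameter fit's pooled shape constants are treated as exact.
* `group_tests` covers the standard designs used with these data but is a
  dispatcher, not a general modelling framework (no mixed effects).
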