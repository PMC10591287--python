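# Methods

This note documents the models, parameter choices, and numerical
decisions behind `freeview`, and what the synthetic-data tests do and
do not establish about recorded data.

## Eye-event detection

Gaze position (x, y in degrees of visual angle, uniform sampling)
is differentiated with Savitzky–Golay filters (`scipy.signal.
savgol_filter`, polynomial order 3, `mode="interp"` so edge samples are
fitted rather than truncated).  Speed is the magnitude of the smoothed
first derivative, acceleration the magnitude of the smoothed second
derivative.

Saccade candidates are maximal runs with speed strictly above 30 °/s;
a candidate qualifies when its peak acceleration exceeds 8000 °/s².
Requiring acceleration above threshold *throughout* a segment would
reject every real saccade, because acceleration crosses zero at peak
velocity; gating the velocity-defined run on peak acceleration is the
physically coherent reading.  Candidates are discarded when peak
velocity exceeds 1500 °/s, peak acceleration exceeds 120 000 °/s²,
duration falls outside [5, 100] ms (rejection bounds strict, as
written: "< 5 ms" drops only strictly shorter), or the start-to-end
gaze shift is below 0.1°.  Inter-saccade intervals, including the
pre-first and post-last intervals, become fixations unless their
internal drift exceeds 1.0°, in which case they are reported in a
separate "unstable" list rather than silently dropped.  Two drift
definitions are implemented — maximal excursion from the first sample
(default) and start-to-end displacement — since the 1.0° rule does not
disambiguate them.  NaN runs (blinks) split the trace; no event spans a
gap.

**Derivative window.**  The filter window is configurable
(`DetectionParams.sg_window_ms`); the default is 15 ms.  A 1° saccade
lasts ~23 ms under the main-sequence model below, and windows much
longer than ~2/3 of the event attenuate its peak acceleration below
the 8000 °/s² gate: at 21 ms the measured recall for ≥ 1° synthetic
saccades drops to ~0.90, at 15 ms it is ≥ 0.99 with precision 1.0.

## Synthetic sessions

The generator emulates the study conditions the pipeline is built for:
60 scene images per session, each with 5 objects (~2° across) drawn
from a 20-object pool and placed > 4° apart on a 38° × 28° gray field;
5-s free-viewing trials; and object-tuned spiking modulated by
fixation order.

* **Saccade kinematics** — minimum-jerk position profile,
  s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, with duration 21 + 2.2·A ms for amplitude
  A in degrees (a standard main-sequence approximation).  Peak velocity
  is 1.875·A/D, peak acceleration 5.77·A/D², so a 1° saccade clears
  both detector thresholds and an 8° saccade peaks near 390 °/s.
* **Fixation durations** — log-normal, median 200 ms (σ = 0.4 in log
  space), floored at 80 ms; about half of first fixations end by
  200 ms.
* **Behavioral policy** — after each fixation the next target is the
  same object with probability 0.35 (a within-object shift of
  0.8–1.4°, matching the ~0.9° second+ saccade amplitudes reported in
  this literature and keeping within-object saccades above the
  detector's acceleration gate), an already-visited other object with
  probability 0.25, the background with probability 0.04 (giving ~90 %
  object fixations overall, the fraction reported for the recorded
  behavior), otherwise an unvisited object.  Weights are renormalized
  over the moves available from the current state.  Landing scatter
  around object centers is Gaussian (SD 0.4°) truncated at 1.2°, inside
  the 1.5° assignment radius.
* **Fixational jitter** — Gaussian, SD 0.05°, rendered as one
  temporally smooth process (10-ms correlation time) over the whole
  trial.  Smoothness matters: white jitter at 1 kHz would add ~50 °/s
  of spurious velocity noise and step discontinuities at event
  boundaries that masquerade as saccades.
* **Spiking** — inhomogeneous Poisson on a 1-ms grid.  Each unit fires
  at its base rate (log-normal, median 8 spikes/s) except in the
  response epoch of each object fixation — onset + latency for one
  response-window length at rate base × object_gain × order_gain,
  followed by an equal-length second epoch further scaled by
  `within_fixation_decay`.  Latency/window are 40/70 ms for V1 and V2
  and 100/50 ms for IT, aligning the two epochs with the areas' FODR
  windows.  Object gains are log-normal (σ = 1), giving object-selective
  tuning.  Order gains multiply the response on the k-th fixation of an
  object (`order_gain[1] = 1` enforced); they can be overridden per
  object, and `per_unit_object` applies heterogeneous later-fixation
  gains per (unit, object) — the tuning-reshape mode.  A gain uniform
  across units rescales a population vector without rotating it, so
  only the heterogeneous mode changes expected cosine similarity or
  sparseness; uniform gains affect those metrics solely through
  sampling noise.
* **Sampling rate** — 1 kHz by default (configurable to 20 kHz).  The
  detector thresholds act on °/s and °/s², so they are rate-independent;
  1 kHz keeps the test suite fast.

What the generator does *not* emulate: saliency-driven target choice,
microsaccades as a separate class, smooth pursuit, eye-blink artifacts
beyond NaN gaps, non-Poisson spiking statistics (bursting, refractory
structure in the generator itself), electrode drift, and correlated
noise across units.  Tests passing on synthetic sessions therefore
validate the pipeline's bookkeeping and statistical machinery, not the
physiological realism of any particular parameter value.

## Fixation categorization

Per trial and per object: the first fixation of an object is *first*;
a fixation on the same object as the immediately preceding fixation is
*second+*; a return to an already-fixated object from another object or
the background is *re-visit*.  Sub-orders: second1/second2 count
positions within a consecutive run, and the counter restarts after
every first or re-visit (the restart is a design choice; the category
definitions do not settle it); revisit1/revisit2 count re-visits per
object within the trial.  The *mix* index is the cumulative count of
fixations on the object, regardless of the second+/re-visit
distinction.  A brute-force history-based oracle over all sequences of
length ≤ 6 on 3 objects + background pins the state machine down
exactly.

Object assignment uses the mean gaze position of the fixation, the
nearest center within 1.5° (inclusive), ties to the lowest object id.
Scene generation guarantees > 4° spacing, so assignment is unique.

## Position-overlap maps

"Variance 0.2°" is read literally as 0.2 deg² (σ ≈ 0.447°); the grid is
object-centered, ± 3° at 0.05°/cell, which covers the 1.5° assignment
radius with < 1 % Gaussian-tail truncation.  The overlap statistic is
the Sørensen-type 2·Σmin(A,B)/(ΣA+ΣB) on peak-normalized maps — the
simple reading that yields exactly 1 for identical maps.

## Unit curation

High-pass: 4th-order Butterworth at 500 Hz, zero-phase (`sosfiltfilt`).
Up-sampling: cubic spline to 200 kHz; alignment: circular shift placing
each waveform minimum at the center sample; snippets whose minimum sits
on an edge are dropped and logged.  Re-clustering: PCA to 3 components,
Gaussian mixtures with 1–3 components chosen by BIC.  Clusters with
> 0.1 % of inter-spike intervals strictly below 1.2 ms are kept but
marked not accepted.  Merging: R² is the squared Pearson correlation of
mean waveforms at zero lag and a merge additionally requires r > 0
(polarity-inverted shapes are distinct units); the merge relation is
closed transitively, so the result is order-independent.  The human
triple-inspection of merges in the original workflow is replaced by a
machine audit log; merges with 0.95 < R² ≤ 0.97 are flagged for review.

## Rate analysis

PFTHs are smooth-then-average: per-fixation 1-ms binned counts are
convolved with a 10-ms-SD Gaussian, then averaged across fixations
(mean ± SEM).  The kernel conserves spike mass for interior spikes to
1e-6 relative tolerance.

FODR windows: for 50-ms windows slid in 5-ms steps over 0–200 ms after
fixation onset, each unit's first-fixation rates are tested against its
later-fixation rates (one-sided Mann–Whitney U for a decrease,
p < 0.01, all fixations regardless of object); the two highest local
maxima of the significant-unit count curve give the window centers
(plateaus count once, at their midpoint; windows are clipped to
[0, 200] ms).  With fewer than two local maxima the per-area defaults
are returned: 40–90 / 110–160 ms for V1 and V2, 100–150 / 150–200 ms
for IT.  The 50-ms width matches the width of all the default windows;
the 5-ms step is a resolution choice.

Rate tables hold one row per (unit, object fixation, window); rates are
spike count over the full nominal 50-ms window even when the fixation
ends earlier — such rows carry a `short` flag so users can filter, since
the source analyses cap at 200 ms but do not state an exclusion.
The per-bin category time course uses two-sided signed-rank tests
across units with Bonferroni correction over the 1-ms bins in
[0, 200] ms (the 10-ms variant of the bin width is available via the
PFTH parameters).  Per-object rate-change counts use two-sided
Mann–Whitney U per (unit, object) with Benjamini–Hochberg FDR at 0.05
across objects within each unit.

## Population metrics

Sparseness is computed after normalizing the rate vector by its
maximum — mathematically identical (the measure is scale-invariant) and
immune to floating-point under/overflow; an all-zero vector is
undefined and returns NaN with a warning.  For category contrasts the
caller restricts each unit's vector to objects with valid mean rates in
all three categories, so categories are compared on identical objects.

Resampled cosine similarity draws, per resample, one single-fixation
rate per (unit, object) — with replacement, since pools may hold
exactly 10 samples while 100 resamples are required — and averages the
cosine over 100 resamples per object pair.  Eligibility: a unit backs
an object only with ≥ 10 samples in every category (so every category's
estimate rests on the same units), and a pair needs ≥ 5 common units.

SVD-AUC normalizes singular values to sum 1, accumulates them, and
averages the cumulative curve at k = 1..K (rectangle rule).  This
quadrature reproduces both limiting statements exactly: a uniform
spectrum gives (K+1)/(2K) → 0.5, a rank-one matrix gives 1.

Cliff's δ is implemented from its definition (no established library
contract): δ = (#{x>y} − #{x<y})/(n_x n_y), checked against pair
enumeration.

Statistical tests are library-backed (`scipy.stats` for signed-rank,
Mann–Whitney U, Kolmogorov–Smirnov; `statsmodels` for FDR).  Paired
differences between categories are computed per item (unit or object
pair); the inference caveat that cosine similarities between pairs
sharing an object are not independent applies to interpretation, not to
the computation.

## Decoding

V1/V2 sessions are meant to be pooled by the caller before decoding;
mix orders are grouped as first, mix2–3, and mix4–6 (beyond mix6
excluded).  Sessions need ≥ 5 simultaneous units and > 10 objects with
≥ 10 fixations in each group.  Per repeat (10 total), an equalized draw
(the minimum group count, without replacement) is scored by stratified
10-fold cross-validation with a shrinkage-regularized linear
discriminant (`solver="lsqr"`, Ledoit–Wolf shrinkage — unit counts are
comparable to sample counts, so the pooled covariance needs
regularization); chance uses one label permutation per repeat, within
category, preserving the category structure.  Stratification is a
choice the 10-fold prescription leaves open; unstratified folds can be
class-empty at these sample sizes.  If a class has fewer members than
folds, the fold count is reduced with a warning.

## Problem sizes in the test suite

The default suite runs sessions of 6–50 scenes × 2–5 repeats with 8–50
units; the 20-session parameter-recovery study uses 50 units and 200
trials per session, and the decoding type-I control uses 100 seeds with
2 repeats of 6-fold cross-validation on 48-sample datasets.  These
sizes were chosen so each check has adequate statistical power while
the whole suite stays interactive.

## Known limitations

* The FODR window finder assumes two separated suppression epochs; on
  flat or single-peaked count curves it falls back to the per-area
  defaults rather than inventing windows.
* Under a later-fixation gain that is uniform across units and objects,
  expected sparseness and expected cosine-of-means are unchanged
  (scale invariance); observed changes in those metrics then reflect
  sampling noise only.  Heterogeneous per-(unit, object) modulation is
  required for systematic selectivity changes, and the generator's
  tuning-reshape mode exists for exactly that contrast.
* The waveform R² merge is evaluated at zero lag after minimum
  alignment by default; a lag-maximized variant is the natural
  extension but alignment makes it rarely necessary.
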