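# freeview

Fixation-order-resolved analysis of neural population activity during
free viewing.

When a primate freely views a scene containing several objects, it
fixates them in a self-chosen order, often returning to objects it has
already inspected.  Repeated exposure suppresses neural responses
(adaptation / repetition suppression), so the population code for an
object is not fixed: it depends on how often and in what order the
object has been fixated within a trial.  `freeview` is a library for
quantifying that dependence in simultaneously recorded spiking data
from visual cortex (V1, V2, IT), from the raw gaze trace up to
population-level decoding.  It is aimed at systems-neuroscience users
analyzing free-viewing sessions, and ships a synthetic-session
generator with full ground truth so every stage of the pipeline can be
validated without recorded data.

## Pipeline

1. **Eye events** (`eye_events`) — gaze speed and acceleration from
   Savitzky–Golay derivative filters; saccades are maximal runs with
   speed > 30 °/s whose peak acceleration exceeds 8000 °/s², screened by
   artifact rules (peak velocity ≤ 1500 °/s, peak acceleration
   ≤ 120 000 °/s², duration 5–100 ms, gaze shift ≥ 0.1°); fixations are
   the inter-saccade intervals whose internal drift stays ≤ 1.0°.
2. **Fixation context** (`fixation_context`) — each fixation is assigned
   to the object whose center is within 1.5° of mean gaze (else
   background) and categorized per object: *first*, *second+*
   (consecutive re-fixation), or *re-visit* (return after fixating
   elsewhere), with sub-orders and a cumulative *mix* index.
   Fixation-position scatter between categories is compared by the
   overlap 2·Σmin(A,B)/(ΣA+ΣB) of peak-normalized Gaussian-sum maps
   (variance 0.2 deg²).
3. **Unit curation** (`unit_curation`) — waveform high-pass (500 Hz),
   cubic up-sampling to 200 kHz, minimum alignment, PCA + Gaussian-
   mixture re-clustering (≤ 3 clusters), rejection of clusters with
   > 0.1 % inter-spike intervals below 1.2 ms, and R² > 0.95 mean-
   waveform merging with an audit log.
4. **Response analysis** (`response_analysis`) — perifixation time
   histograms (1-ms bins, 10-ms-SD Gaussian smoothing per fixation,
   then averaged); the two 50-ms fixation-order-dependent response
   (FODR) windows located from the count of units with significant
   first-vs-later rate decreases (defaults 40–90 / 110–160 ms for
   V1 and V2, 100–150 / 150–200 ms for IT); per-fixation FODR rate
   tables.
5. **Population metrics** (`population_metrics`) —
   lifetime sparseness `S_life = (1 − a)/(1 − 1/N)` with
   `a = ((Σrᵢ)/N)² / (Σrᵢ²/N)`; cosine similarity
   `Sim_jj' = R_j·R_j' / (|R_j||R_j'|)` between per-object population
   vectors, averaged over 100 random single-fixation draws per
   (unit, object); SVD-AUC of the object × unit rate matrix (area under
   the normalized cumulative singular-value curve, 0.5 = uniform
   spectrum, 1 = rank one); Cliff's δ effect sizes.
6. **Discrimination** (`discrimination`) — object identity decoded from
   single-fixation population vectors with a shrinkage-regularized
   linear discriminant, stratified 10-fold cross-validation over 10
   equalized draws, chance level from within-category label
   permutation.

## Worked example

```python
import freeview as fv

# a synthetic IT-like session: 100 five-second trials, 30 units,
# later fixations of an object suppressed to 0.8x
mod = fv.ModulationSpec(order_gain={1: 1.0, 2: 0.8})
bundle = fv.generate_session(seed=7, n_scenes=20, n_repeats=5,
                             n_units=30, modulation=mod)

labeled, rates = fv.analyze_session(bundle)   # detect, label, tabulate
m = fv.order_modulation_summary(rates, rng=7)
print(f"later/first rate ratio: {m.rate_ratio:.3f}")
print(f"similarity change (later - first): {m.similarity_diff:+.3f}")
```

prints

```
later/first rate ratio: 0.809
similarity change (later - first): -0.049
```

The injected 0.8 suppression is recovered as a later/first firing-rate
ratio of 0.809 through the full detection → labeling → rate pipeline,
and the population vectors for different objects become less similar on
later fixations (−0.049 over 153 object pairs): lower, noisier rates
push resampled population vectors apart even when mean tuning is only
rescaled.  The population complexity of the same session's first
fixations, `fv.svd_auc(...)` on the object × unit rate matrix, gives an
AUC of 0.751 — between the uniform-spectrum floor of 0.5 and the
rank-one ceiling of 1.

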