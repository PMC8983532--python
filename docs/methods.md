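# Methods

This note documents the models, estimators and numerical choices behind
`desmoquant`, what the synthetic-data generators do and do not emulate, and
the known limitations of each quantification.

## Line-scan quantification of junctional enrichment

**Model.** A line scan is a short oriented profile crossing a bicellular
border perpendicular to its local direction. The profile is split into a
junctional band centred on the border crossing and cytoplasmic bands at both
ends; the enrichment ratio is the junctional-band mean over the
cytoplasmic-band mean. No background subtraction is performed — the ratio is
invariant under global multiplicative rescaling (gain, exposure), but an
additive camera offset would bias it toward 1, so offset-corrected images
should be supplied.

**Border tracing.** Bicellular interfaces are traced on the cell label mask:
a trace consists of the pixels of the lower-numbered cell whose
8-neighborhood contains the partner label, ordered by greedy chaining.
Pixels whose neighborhood contains three or more distinct cell labels
(tricellular corners) are excluded, since scans there would mix three
compartments.

**Defaults and rationale.**

| parameter | default | rationale |
|---|---|---|
| pixel size | 0.161 µm | widefield acquisition setting of the quantified micrographs |
| segment length | 31 px (~5 µm) | spans border plus flanking cytoplasm at that magnification |
| segment width | 3 px | averages out single-pixel noise without blurring the peak |
| spacing | 10 px | near-independent samples along one border |
| junctional band | central 3 × border-width samples (border width 1 by default) | covers the crossing plus tracing uncertainty |
| cytoplasmic band | outer 25% of samples per end | far enough from the border to be junction-free |

The junctional band must be narrower than the enriched stripe it measures,
or the band mean dilutes below the true peak ratio; recovery tests therefore
render borders wider (7 px) than the 3-sample band. Sub-pixel sampling uses
bilinear interpolation; quartiles in the per-group summary use linear
interpolation (type 7). Group comparisons use the two-sided Mann–Whitney
rank-sum test.

## Irregularity score

For border intensities I₁…I_N with mean x̄ > 0:

    score = [ (1/N) · Σᵢ max(Iᵢ − x̄, 0) ] / x̄

Only supra-average pixels contribute (one-sided deviation), the sum is
averaged over *all* N border pixels, and the result is normalized by x̄ so
staining strength cancels. Properties (all enforced by tests): score ≥ 0,
score = 0 exactly for constant profiles, scale invariance, and the upper
bound (max I − x̄)/x̄.

Two readings of "the average deviation" are possible: averaging the excess
over all pixels (default, `denominator="all_pixels"`) or only over the
supra-average pixels (`denominator="bright_pixels"`). Both are implemented;
the default divides by N because the averaging step is described over all
membrane pixels.

The score is **permutation invariant** — it measures amplitude dispersion,
not spatial frequency. A border whose bright pixels are scattered scores the
same as one where they are clustered; "irregularity" here means "dominance
of supra-average intensities", and spatially-resolved alternatives
(autocorrelation, spectral measures) are deliberately out of scope.

## Keratin skeleton density

Pipeline: threshold → thin → graph → densities.

* **Threshold**: Otsu by default, fixed value as override; the applied
  threshold is recorded so identical parameters can be enforced across all
  groups of one analysis (the pipeline runner applies one setting per run).
* **Thinning**: two-subiteration morphological thinning to an 8-connected,
  unit-width skeleton (no 2 × 2 foreground block); thinning is idempotent.
* **Graph**: skeleton pixels with ≥ 3 skeleton neighbors are junction
  pixels; adjacent junction pixels are merged into one node (thick crossings
  otherwise over-count). The remaining pixels decompose into branches. Every
  skeleton pixel belongs to exactly one branch or one junction node.
* **Spur pruning**: end-point branches shorter than `min_branch_px`
  (default 3 px) are removed iteratively with re-thinning, suppressing
  noise-induced 1–2 px stubs; pruning is idempotent and disabled at 0.
* **Densities**: bundles (= branches) and bundle junctions are counted per
  ROI area (pixel count × pixel size²); a branch or junction is counted when
  ≥ 50% of its pixels fall inside the ROI. Whether "number of bundles"
  should count branches or connected components is ambiguous in common
  usage; branches are the primary output (matching skeleton-analysis
  convention) and the connected-component count is emitted alongside.

**Resolution-limited comparison.** Two branch points closer than the
rendered filament width, and terminal stubs shorter than it, cannot be
resolved by any pixel-level skeleton. `coarse_counts(min_sep)` therefore
coarsens a branch graph to a stated resolution (contracting short
junction–junction edges and dropping short terminal edges) on *both* the
ground-truth arrangement graph and the recovered skeleton graph before
comparing counts; recovery tests use 6 px for filaments rendered with a
1 px Gaussian profile.

## AFM force spectroscopy

**Curve model (synthetic).** Retract curves are piecewise linear: a contact
ramp reaching the setpoint (0.5 nN) at full indentation with stiffness
10 pN/nm (contact point at indentation = setpoint/stiffness), then for
binding curves an adhesive segment out to the step position — by default a
constant-force membrane-tether plateau, optionally a linear ramp-to-rupture
— ending in a single instantaneous rupture back to baseline. Acquisition
metadata mirrors the force-mapping protocol (Z-length 1.5 µm, pulling speed
10 µm/s, contact time 0.1 s, nominal spring constant 0.03 N/m, tip radius
20 nm). Noise is additive i.i.d. Gaussian on force. Multi-rupture curves,
worm-like-chain elasticity, drift and hysteresis are not modelled.

**Contact point.** Robust baseline = median of the outer 30% of extension;
baseline scatter σ = 1.4826 × MAD. The repulsive contact regime (upper 75%
of the ramp) is fitted linearly and intersected with the baseline. A curve
with no sample above baseline + 5σ has no contact region and raises an
error. The estimator is exactly equivariant under z shifts.

**Event detection.** On the baseline-subtracted retract force, rolling
medians over an 8-sample window give pre- and post-levels around each
candidate index. An unbinding event requires (i) a sustained adhesive
excursion: pre-level < −kσ, and (ii) a return toward baseline: jump > kσ,
with k = `threshold_sigma` (default 6) and σ the MAD-based scatter of the
final 20% of extension. Contiguous candidates form one event; the rupture
index is refined to the largest single-sample rise. Event force = post-step
median − pre-step median (adhesive steps are positive magnitudes); step
position = rupture z − contact point. The 6σ operating point keeps the
false-positive rate on non-binding curves below 1% while detecting ≥ 95% of
events with force ≥ 10 × baseline σ.

**Force maps.** A map is a grid of curves (default 6 × 2 µm at 0.1 µm →
1200 pixels) with a junctional border-stripe mask. Binding frequency is the
fraction of pixels with ≥ 1 event (per-pixel binding is binary even when a
curve holds several events); the distribution coefficient is
BF_border/BF_surface, reported as undefined (None) with pixel counts when no
surface pixel binds. The published formulation of the coefficient is not
fully specified in the protocol this mirrors; the binding-frequency ratio
implemented here matches its verbal definition and is labelled as such in
outputs.

## Dispase fragment counting

Foreground components (8-connectivity) of a thresholded or binary well
image; components below `min_size_px` (default 50) are discarded as debris —
an automated, disclosed stand-in for the by-eye exclusion applied during
manual counting. Counts are invariant to rotation and to intensity rescaling
above threshold. Conditions are summarised as mean ± SEM (SEM reported as
NaN for single-well groups) and compared pairwise with Student's t test.

## Statistics

* `compare_groups(..., test="auto")` mirrors the published decision rule:
  a two-sided F test on the variance ratio at α = 0.05 selects Student's
  t test (equal variances) or the Wilcoxon–Mann–Whitney test.
* Rank-sum p-values are exact for n ≤ 8 per group — every C(n₁+n₂, n₁)
  group assignment is enumerated with midranks for ties — and otherwise use
  the tie-corrected normal approximation with continuity correction.
* `anova_bonferroni` runs one-way ANOVA, then all pairwise t tests with
  p-values multiplied by the number of pairs and capped at 1 (adjusted
  p ≥ raw p always).
* Star thresholds: the figure-legend convention (* p < 0.05, ** p < 0.01,
  *** p < 0.001) is the default; a stricter *** at p < 0.005 appears in some
  methods texts and is available via `thresholds=METHODS_THRESHOLDS`.
  Inequalities are strict.
* Boxplot summaries report the full range (min–max), not 1.5 IQR whiskers.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the estimators consume,
not photorealistic microscopy:

* **Monolayers** are nearest-seed tessellations of random, well-separated
  seed points — closed convex-ish cells suitable for perpendicular line
  scans. Border enrichment is a flat-top stripe; patchiness multiplies
  contiguous border arcs by 1 + patch amplitude. No point-spread function,
  no multi-channel cross-talk, no autofluorescence gradients.
* **Filament networks** grow as straight rays with stochastic branching
  (30–60° branch angles). Degenerate geometry that no skeleton analysis
  could resolve is excluded by construction: branches must reach 3 growth
  steps, spawn points keep clear of filament ends and of each other, and a
  filament approaching an existing one at a glancing angle (< 30°)
  terminates with a standoff gap instead of producing an unresolvable
  near-parallel merge. The exact arrangement graph (computed geometrically,
  independent of any image processing) is the recorded ground truth.
  Rendered ridge intensity is normalized to the single-filament peak so
  crossings do not rescale the image.
* **Force curves/maps** embed exactly one rupture per binding curve with
  known contact point, force and step position; per-pixel binding is
  Bernoulli with separate probabilities on and off the border stripe.
* **Fragment images** place non-touching elliptical fragments plus debris
  specks strictly smaller than the minimum fragment size, so the size filter
  recovers the true count exactly.

Passing recovery tests on these data therefore demonstrates correctness of
the estimators under the stated models — not robustness to uneven
illumination, segmentation errors, filament curvature, multi-rupture
cascades or other real-data complications, which remain the user's
responsibility to assess.

## Problem sizes used in the validation suite

Monolayers 256² px with 5 cells (~70 line scans); filament networks 256² px
with 5 seed filaments (4–6 networks per recovery test); 200 binding curves
(1000 samples) and 500 non-binding curves (800 samples) for the detector's
operating point; one to two full 1200-pixel force maps (600 samples/curve)
for map statistics; fragment wells 512² px with up to 37 fragments. These
sizes give stable Monte-Carlo estimates for every tolerance tested while
keeping the whole suite around ten seconds on one CPU.
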