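# desmoquant

Quantification toolkit for desmosome hyperadhesion studies in epithelial
monolayers. Desmosomes are cell–cell junctions that anchor keratin
intermediate filaments via desmosomal cadherins (desmogleins Dsg1/Dsg3) and
plaque proteins (desmoplakin, plakophilins); during maturation they acquire a
calcium-independent, *hyperadhesive* state. Establishing how keratin isotype
composition controls this state requires a set of bespoke quantifications on
immunofluorescence images, AFM force maps and dispase dissociation assays.
`desmoquant` implements all of them as a tested, reusable pipeline, together
with a synthetic-data generator that produces every input with known ground
truth so that each estimator can be validated by parameter recovery.

## What it computes

**Junctional enrichment (line scans).** Short intensity profiles are placed
perpendicular to traced bicellular borders. For each scan, the ratio

    R = I_junctional / I_cytoplasmic

of mean junctional-band to mean cytoplasmic-band intensity quantifies
enrichment of a stained protein at the contact; profiles can be normalized to
the cytoplasmic mean. Ratios are summarised per group as boxplot statistics
(median, Q1–Q3, full range).

**Membrane irregularity score.** For border intensities I₁…I_N with mean x̄,

    score = [ (1/N) Σᵢ max(Iᵢ − x̄, 0) ] / x̄

i.e. the mean one-sided excess over the border mean, normalized by the mean.
A score of 0 means perfectly uniform staining; patchy, clustered staining
scores higher. The score is scale invariant and depends only on the
intensity distribution (see `docs/methods.md`).

**Keratin network density.** Filament images are thresholded (same
parameters across groups), thinned to unit-width skeletons, and decomposed
into a branch/junction graph; bundle density and junction density are counts
per ROI area in µm².

**AFM force spectroscopy.** Retract force–distance curves are analysed for
the tip–sample contact point, unbinding events (step magnitude = unbinding
force in pN; distance from contact = step position in nm, large values
indicating membrane tethers), per-map binding frequency (fraction of pixels
with ≥ 1 event) and the junctional distribution coefficient
BF_border / BF_surface over a 6 × 2 µm, 1200-pixel force map.

**Dispase fragment counting.** Monolayer fragments after enzymatic release
and mechanical stress are counted as 8-connected components with a disclosed
debris size filter; conditions are compared with Student's t test.

**Statistics.** Two-tailed t tests, Wilcoxon–Mann–Whitney rank-sum tests
(exact permutation enumeration for n ≤ 8, tie-corrected normal approximation
otherwise), one-way ANOVA with Bonferroni-adjusted pairwise comparisons, and
significance stars (* p < 0.05, ** p < 0.01, *** p < 0.001).

## Worked example

```python
import numpy as np
import desmoquant as dq
from desmoquant.synthetic import CurveSimParams, MapSimParams

# synthetic monolayer: junctional enrichment 3x, SNR 10
params = dq.MonolayerParams(image_shape=(256, 256), n_cells=5,
                            enrichment_ratio=3.0, border_width_px=7,
                            noise_sd=10.0, rng_seed=2)
image, mask, truth = dq.generate_monolayer(params)
ratios = [dq.measure_line_scan(image, seg).ratio
          for tr in dq.trace_borders(mask)
          for seg in dq.place_line_scans(tr, spacing_px=10, length_px=31, width_px=3)]
print(f"n line scans: {len(ratios)}")
print(f"median junction/cytoplasm ratio: {np.median(ratios):.3f} (true 3.0)")

# synthetic force map: 2x more binding on the border stripe
fmap = dq.generate_force_map(MapSimParams(
    p_bind_border=0.6, p_bind_surface=0.3,
    curve_params=CurveSimParams(n_points=600, baseline_noise_sd_pN=5.0),
    rng_seed=3))
st = dq.map_statistics(fmap)
print(f"force map: {fmap.n_curves} curves")
print(f"binding frequency: {st.binding_frequency:.3f}")
print(f"distribution coefficient: {st.distribution_coefficient:.2f} (true 2.0)")
```

Output:

```
n line scans: 71
median junction/cytoplasm ratio: 2.998 (true 3.0)
force map: 1200 curves
binding frequency: 0.382
distribution coefficient: 1.94 (true 2.0)
```

The recovered median ratio matches the generator's enrichment within 0.1%,
and the distribution coefficient estimate (1.94) lies within one binomial
standard error of the true border/surface binding-probability ratio (2.0).

## Command line

Every stage can be driven from a YAML/JSON run configuration:

```bash
desmoquant simulate  --config run.yaml   # synthetic data + ground truth
desmoquant linescan  --config run.yaml   # junctional/cytoplasmic ratios
desmoquant report    --config run.yaml   # all configured stages + summary
```

Outputs (per-segment and per-group CSVs, QC images, a run log and a manifest)
are written under the configured `outdir`; reruns with the same seeds are
byte-identical.

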