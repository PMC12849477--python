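# Methods

This note documents the models behind `comphet`, the parameter defaults and
why they were chosen, the numerical conventions, and the limits of what the
synthetic tests demonstrate.

## The measurement problem

Competence-gene induction in a bacterial population can be gradual and
heterogeneous: instead of a bimodal ON/OFF split, the single-cell
fluorescence distribution of a promoter reporter stays unimodal while its
upper tail grows over time. The package quantifies that pattern from three
measurement types — microscopy fields, flow-cytometry samples, and
population-level plate counts / plate-reader kinetics — and provides a
generator that emulates each measurement's statistical structure with known
ground truth.

## Single-cell intensity model

Per-cell fluorescence is a two-component mixture on the log10 scale:
a cell is "induced" with probability *p* and draws
log₁₀(I) ~ N(μᵢ, σᵢ), otherwise it draws from the baseline component
N(μ_b, σ_b) with μᵢ > μ_b. This is the minimal model that produces a
unimodal, right-skewed distribution whose tail mass grows with *p*; at the
default separation (μ_b = 2.8, μᵢ = 3.6, σ = 0.12, arbitrary log-counts)
the mixture stays visibly unimodal for the small induced fractions
(p ≤ 0.05) the analyses target. It is deliberately phenomenological: no
gene-regulatory feedback is simulated, so the generator can say nothing
about mechanism, only about what the statistics pipeline should recover.

The three default strains mirror a standard experimental design: a
competence reporter whose induced fraction grows 0 → 0.01 → 0.05 across
three timepoints, a dim non-fluorescent wild type, and a brighter
constitutive control, both with p = 0 throughout. Flow samples default to
100,000 events, matching routine cytometer acquisition; microscopy defaults
(6 fields × 60 cells per strain and timepoint) put the pooled per-sample
cell counts in the few-thousand range typical of segmented image datasets.

## Microscopy rendering and quantification

Cells render as non-overlapping disks (radius ~ N(6, 1) px, floor 1 px)
because the organism of interest is a coccus and samples are sonicated to
disperse aggregates before imaging — which is also why no spatial
statistics are offered. The expected image is background (default 200
counts, optional linear gradient along x) plus per-cell intensity inside
each disk; Poisson shot noise and Gaussian read noise (σ = 2) are applied,
then the image is rounded and clipped into the bit depth (default 16-bit;
exposure and bit depth are generator conventions, not measured values).

The quantification pipeline is fixed in this order:

1. **Contrast stretch** to [0, 1] between the image's 2nd and 98th
   percentiles. This feeds segmentation only; intensity is always measured
   on the raw image, so changing the stretch percentiles cannot change a
   measured mean (tested as the "measurement purity" invariant).
2. **Segmentation**, default classical: Gaussian smoothing (σ = 2), Otsu
   threshold, small-object removal (< 4 px), hole filling, Euclidean
   distance transform, peak markers (min separation 7 px ≈ cell radius),
   watershed. A registry seam (`register_segmenter`) accepts any function
   mapping a stretched image to a label map, so a pretrained deep-learning
   segmenter can be swapped in without touching the rest of the pipeline;
   none is required or bundled.
3. **Smallest-3% filter**: exactly ⌊0.03·N⌋ objects of smallest area are
   removed, ties broken by label order, applied per image (a pooled variant
   is a caller choice). The floor rule makes N < 34 remove nothing.
4. **Central ROI**: objects whose centroid lies strictly inside the circle
   of radius 0.5·min(W, H) centered in the frame. min() resolves the
   ambiguity for non-square images (the circle always fits); the centroid
   test (rather than a pixel mask) keeps boundary cells wholly in or out,
   avoiding truncated-cell intensity bias. The size filter runs before the
   ROI because debris exclusion is a global property of the field.
5. **Mean raw intensity** per retained label, then **per-image min–max
   scaling** to relative intensity 0–100%.

Operating envelope of the classical segmenter: the 2–98% stretch assumes
cell pixels occupy more than ~2% of the field. Below that, the 98th
percentile falls inside the background distribution, the stretch amplifies
background noise across the full [0, 1] range, and Otsu can fabricate
background objects. Default fields (≈4% cell coverage) sit inside the
envelope; very sparse fields need a lower `p_high` or an external
segmenter.

A consequence of per-image min–max normalization worth knowing: relative
intensities are anchored by each image's brightest cell. If the reference
timepoint contains *no* induced cells, the later appearance of bright cells
rescales every image's axis, compressing baseline cells downward — so the
reference-anchored exceedance delta on the relative scale can be ≈ 0 or
negative even when induction is real. In real datasets a small
high-expressing tail is typically present already at the reference
timepoint (pre-activated cells in stationary-phase precultures), which
anchors the scale and yields positive deltas. The flow-cytometry route
(absolute log-fluorescence, no per-image rescaling) does not have this
failure mode and is the primary carrier of the end-to-end shift check.

## Shift statistic

For each strain, thresholds are the chosen percentiles of its own
reference-timepoint distribution (75/99 for cytometry, 95/99 for
microscopy, matching common practice of one moderate and one stringent
cutoff). Exceedance is the percentage of values **strictly greater** than
the threshold — with continuous data the choice of strict vs non-strict is
immaterial; with ties it is fixed and documented. Deltas are
fraction(late) − fraction(reference) in percentage points. Thresholds and
fractions always use the full measured sample; the 250-event / 150-cell
subsampling exists only to give beeswarm panels comparable visual density,
and a flag-free code path guarantees it cannot leak into statistics.

One percentile convention is used package-wide: linear interpolation
between order statistics (`numpy.percentile(..., method="linear")`). For a
continuous sample of size ≥ 10⁴ this makes exceedance of the sample's own
q-th percentile equal (100 − q)% to within ±0.5 pp.

Skewness (standard moment-based, via `scipy.stats.skew`) is reported
descriptively only; no unimodality test is performed.

## Transformation-frequency kinetics

TF = (selective CFU × selective dilution) / (total CFU × total dilution).
The detection limit is the spontaneous-reversion frequency measured on
no-DNA control plates, floored at 10⁻⁹ (the typical reversion scale for a
point-mutation marker); a measurement whose selective count does not exceed
the control-expected background is *censored* at the limit — reported as
"≤ limit", never as zero, so log-scale analyses stay defined and censored
points never enter slope fits.

The maximum induction rate is the largest slope of a sliding-window
(default 3 consecutive uncensored points) least-squares fit of log₁₀ TF vs
time. The window average necessarily attenuates the instantaneous maximum
slope of a saturating trajectory; at the default generator conditions
(log-logistic rise 10⁻⁸ → 10⁻², max slope 0.5 log₁₀/h, 4-h sampling) the
attenuation is ~10–13%, and it grows when the onset falls between sampling
points — a sampling-phase effect to keep in mind when comparing conditions
sampled on different grids.

The 0-h sample of a typical assay comes from a rich-medium preculture
rather than the induction medium; callers should tag it with a distinct
condition label and it is excluded from slope windows when censored.
OD-at-peak uses the earliest timepoint on ties.

## Reporter curves and 4PL fitting

MUG (β-galactosidase substrate) fluorescence is normalized pointwise to
Nile Red (biomass proxy); non-positive Nile Red values are masked with a
warning. The normalized curve is fit with the four-parameter logistic

    f(t) = a + (d − a) / (1 + (t/c)^(−b)),

(a, d asymptotes; c > 0 inflection time; b ≠ 0 hill slope; d > a and b > 0
give an increasing curve). The fit window defaults to [first timepoint,
time of the global maximum] to exclude the post-plateau decline caused by
substrate depletion, which the generator reproduces by capping raw MUG at a
substrate capacity and decaying it afterwards. Initialization is
data-driven (a = min, d = max, c = mid-rise crossing, b = ±2 by trend);
fitting is `scipy.optimize.curve_fit` with c bounded positive. The
steepest-slope ("peak") time uses the closed form
t\* = c·((b−1)/(b+1))^(1/b) for |b| > 1 — verified against dense numeric
differentiation in the test suite — otherwise a grid argmax of |f′|.
Constant input returns a flagged degenerate fit with zero slope rather than
an error, since plateaued wells are routine. The peak-time-vs-inoculum
table reports a Spearman rank correlation descriptively (the expected
relation is inverse: denser inocula peak earlier).

## Seeds and reproducibility

Every generator takes an explicit seed; scenarios derive one seed per stage
from the scenario seed through `numpy.random.SeedSequence` keyed by a
stable SHA-256 digest of the stage tag (so derived seeds are independent of
interpreter hash randomization). Stage seeds are logged in the run
manifest together with a config hash and input checksums; identical config
and seed produce byte-identical CSV outputs, and all file writes are
atomic (temp-then-rename).

## Problem sizes

The test suite and the acceptance script run deliberately scaled study
sizes chosen to keep the full validation loop fast while preserving the
statistical structure: 100,000-event FC samples where tail fractions
matter, 10 fields × 50 cells for segmentation recovery, 50 seeded
repetitions for 4PL noise recovery, 20 for induction-rate recovery, and a
down-scaled end-to-end scenario config (`examples/scenario_small.yaml`)
for CLI runs.

## Known limitations

- The generator is phenomenological; passing tests demonstrate that the
  *pipeline* recovers known ground truth under the stated noise models, not
  that any particular biological dataset satisfies those models. Real
  images differ in ways the renderer does not emulate: focus drift,
  aggregates that survive sonication, non-disk morphologies, autofluorescent
  debris, uneven illumination beyond a linear gradient.
- The classical segmenter targets well-separated coccoid cells; touching or
  overlapping cells, rods, or dense fields need the adapter seam.
- FCS support is read-only and covers FCS 3.0/3.1 list-mode files with
  uniform float/double or 16/32-bit integer data; no compensation or gating
  hierarchy is applied.
- TF censoring treats the control-derived background as exact; with very
  few control colonies the limit itself is noisy, and no uncertainty is
  propagated onto it.
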