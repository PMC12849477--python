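# comphet

Single-cell competence heterogeneity analysis for bacterial reporter-strain
experiments.

Natural competence — the ability of bacteria to take up extracellular DNA —
can develop gradually and heterogeneously across a population rather than
through an abrupt bistable switch. Detecting that pattern requires
quantitative tools on three levels: per-cell fluorescence from microscopy,
distribution-shift statistics from flow cytometry, and population kinetics
(transformation frequency, promoter-activity curves). `comphet` implements
all three as a tested, seedable pipeline, driven by a synthetic-data
generator with known ground truth, so every stage can be validated without
access to raw instrument data. It is aimed at microbiologists analysing
competence (or any promoter-activity) reporter strains in coccoid bacteria
such as *Micrococcus luteus*.

## What it computes

**Image quantification** (`comphet.image_quant`) — a fixed pipeline per
field: 2nd–98th percentile contrast stretch (segmentation input only) →
classical segmentation (Gaussian smoothing, Otsu threshold, distance
transform, peak-seeded watershed; external segmenters pluggable) → removal
of the smallest 3% of objects by area → central circular ROI filter
(centroid test, radius 0.5·min(W,H)) → per-cell mean intensity on the *raw*
image → per-image min–max scaling to relative intensity in [0, 100]%.

**Shift statistics** (`comphet.heterogeneity_stats`) — the
percentile-exceedance shift statistic: fix thresholds at chosen percentiles
(e.g. 75th/99th for cytometry, 95th/99th for microscopy) of a reference
timepoint's distribution, then report, per strain and threshold,

&nbsp;&nbsp;Δpp = % of cells above threshold at the late timepoint − % above it at the reference,

always computed from the full measured population; seeded display
subsampling (250 events / 150 cells) affects plots only.

**Kinetics** (`comphet.kinetics`) — transformation frequency
TF = transformant CFU / total CFU with detection-limit censoring from
no-DNA reversion controls (default limit 10⁻⁹); maximum competence
induction rate as the sliding-window least-squares slope of log₁₀ TF per
hour; OD at peak transformability; MUG/Nile-Red reporter normalization; and
four-parameter logistic fits
f(t) = a + (d − a) / (1 + (t/c)^(−b)) with the steepest-slope time
t\* = c·((b−1)/(b+1))^(1/b) for b > 1.

**Synthetic data** (`comphet.synthetic_data`) — a two-component lognormal
intensity mixture (baseline + induced fraction), rendered microscopy fields
with Poisson/Gaussian noise and per-cell ground truth, flow-cytometry
samples, logistic growth, log-logistic TF trajectories with Poisson plating
noise, and reporter curves with substrate-depletion decline. All randomness
derives from one scenario seed.

## Worked example

Simulate the default study (three strains — a competence reporter whose
induced fraction grows 0 → 0.05 across 2 h/7 h/20 h, plus wild-type and
constitutive controls — 100,000 events each) and compute the
flow-cytometry shift report:

```python
import numpy as np
from comphet import heterogeneity_stats as hs, synthetic_data as sd

scn = sd.default_scenario(seed=42)
scn.include_microscopy = False          # FC route only for this example
result = sd.simulate_scenario(scn)

samples = []
for tab in result.fc_samples:
    logs, dropped = hs.log10_events(tab.values)
    samples.append(hs.SampleDistribution(tab.strain, tab.timepoint_h, logs))

report = hs.shift_report(samples, reference_timepoint=2.0,
                         late_timepoint=20.0, levels=[75, 99])
print(report.deltas.to_string(index=False))
```

prints

```
        strain  level  delta_pp
comEA_reporter   75.0     3.932
comEA_reporter   99.0     5.030
      wildtype   75.0     0.163
      wildtype   99.0    -0.039
  constitutive   75.0     0.143
  constitutive   99.0     0.006
```

Only the competence reporter is enriched above its own reference
thresholds: ~5 pp more of its cells exceed the 2-h 99th percentile by
20 h (a true induced fraction of 0.05 minus the ~1% baseline tail already
above the threshold at 2 h, plus sampling noise), while both controls stay
near zero — the signature of gradual, heterogeneous induction.

The same analysis runs end to end from the shell:

```sh
comphet run-all --config examples/scenario_small.yaml --out out/ --seed 42
```

which writes event tables, per-cell CSVs, shift reports (CSV/JSON),
beeswarm figures, TF series and 4PL fit parameters, plus a run manifest
with per-stage seeds and input checksums.

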