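# azquant

Quantitative analysis of voltage-gated Ca²⁺ channel abundance and release
probability at single synaptic active zones (AZs), built around the
*Drosophila* larval neuromuscular junction (NMJ) assay suite: fluorescent
punctum detection and intensity measurement, optical quantal analysis of
stimulus-locked postsynaptic events, and homeostatic-plasticity analyses
(paired before/after single-AZ quantification, additive-vs-multiplicative
scaling discrimination, tercile change analysis, population comparisons,
ratiometric Ca²⁺ transients, and quantal electrophysiology).

Every analysis stage is exercised against a first-class synthetic-data
module with known ground truth, so the whole chain is testable without any
microscope data.

## Who this is for

Labs doing single-synapse imaging at the fly NMJ (or any preparation with
punctate presynaptic markers and optically resolvable quantal events) who
want a scripted, deterministic, provenance-tracked replacement for
interactive Fiji workflows — and a simulator to validate parameter choices
before touching real data.

## The quantities at the core

- **Punctum intensity.** After background subtraction and a light Gaussian
  filter (σ = 0.75 px), puncta are found with prominence-based local-maxima
  detection (two peaks merge when the dip between them is shallower than the
  noise tolerance), segmented by marker-based watershed above a threshold,
  and measured on the *unfiltered* background-subtracted image:
  `sum_intensity = mean × area`. A binary mask from one channel transfers
  1:1 to any co-registered channel or timepoint.
- **Release probability.** Per AZ over *n* stimuli,
  `Pr = (# distinct stimuli with an assigned event) / n`. Events are
  assigned to the nearest punctum centroid by Euclidean distance; per-NMJ
  Pearson *r* between sum intensity and Pr quantifies how predictive channel
  abundance is of release.
- **Scaling discrimination.** For paired baseline/after intensities
  (vehicle-corrected by the mean after/before ratio of a mock-treated
  group), the additive model *y = x + c* (*c* = mean Δ) and the
  multiplicative model *y = m·x* (*m* = Σxy/Σx²) each have one parameter,
  so the smaller residual sum of squares selects the model; the
  unconstrained least-squares line with a heteroscedasticity-robust slope
  CI is reported alongside.
- **Transients and quanta.** Ratiometric traces R(t) = rhod/AF647, sweep
  averaging, peak ΔR and exponential decay τ (QC: τ < 250 ms), train
  plateau, raw 3×MAD outlier exclusion; quantal content = mean EJP / mean
  mEJP per recording, averaged across NMJs.

## Worked example

Run the full synthetic pipeline (simulate → detect → map Pr → paired
analysis) and summarize it:

```
$ azquant run --out demo --seed 42
$ azquant report --run-dir demo
azquant 0.1.0 run, seed 42
  simulate: n_az=100, n_events=934, n_stimuli=100
  puncta: n_puncta=100
  release: n_assigned=934, n_unassigned=0, median_pr=0.07
  paired: selected_model=multiplicative, vehicle_factor=1.014941608276595
  intensity-Pr average r = 0.913
  scaling: multiplicative (slope 1.558, R2 0.964)
```

Reading: 100 planted AZs were all recovered as puncta; 934 postsynaptic
events over 100 stimuli map to a median per-AZ release probability of 0.07
for this map, strongly correlated with punctum intensity (r = 0.91); and
the paired before/after table (simulated here with a 1.5× proportional
perturbation) is correctly classified as multiplicative scaling with a
fitted slope near 1.5. `demo/` holds every intermediate table (CSV), image
(16-bit TIFF), fit (JSON), the resolved config, and a provenance record.

Individual stages are available as `azquant simulate / puncta / events /
map-pr / paired / compare / transients / ephys`, each a thin wrapper over
the `azquant.*` library modules.

## Layout

```
src/azquant/
  synthetic.py    ground-truth generators (AZ maps, images, movies,
                  paired tables, transients, ephys)
  puncta.py       detection, segmentation, measurement, mask transfer
  release.py      event detection, NN assignment, Pr, correlations
  plasticity.py   vehicle correction, scaling fit, terciles, populations
  transients.py   ratio traces, peak/tau, plateau, MAD filter, QC
  ephys.py        quantal content and group summaries
  io.py/config.py/pipeline.py/cli.py   TIFF+CSV+JSON IO, YAML config,
                  seeded orchestration, `azquant` CLI
docs/methods.md   model, parameter, and design documentation
```
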