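# Methods

This note documents the models, defaults, and design decisions behind
`azquant`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic forward model

The generators in `azquant.synthetic` define the study conditions every
downstream stage is validated against.

**AZ maps.** `gen_az_map` places `n_az` centers uniformly in a
(width, height) field by rejection sampling with a minimum pairwise spacing
(default 8 px; an error is raised after a bounded number of attempts).
Channel levels are gamma-distributed — right-skewed, so most AZs carry
low-to-moderate signal and a minority are bright — with defaults
shape 2, scale 300 a.u., plus an offset of 250 a.u. The offset is the
fluorescence floor of a formed punctum: every AZ in this preparation has a
resolvable punctum, so even the dimmest spot sits above the camera noise
(peak amplitude ≥ 5× the default read-noise SD at the default PSF width).
A second channel is generated by mixing the standardized level signal with
independent noise at a configurable Pearson correlation (default r = 0.95,
the scaffold-protein/channel coupling regime), then clipped positive.

**Release probability coupling.** Pr is affine in the min–max-normalized
level, `Pr = clamp(0.5·z + ε, 0.001, 1)` with Gaussian coupling noise
ε (default SD 0.03). The normalization makes the coupling invariant to the
intensity offset and units. With the default gamma levels this puts the
median per-AZ Pr near 0.11 with roughly 90 % of AZs between 0.01 and 0.5 —
the skewed low-Pr regime reported for this synapse. The affine form is a
modeling choice: only the correlation between channel level and Pr is
empirically established, not a functional form, so the slope, intercept,
noise SD, and clamp are all configurable.

**Images.** Each AZ renders as an isotropic 2-D Gaussian (default
σ = 1.5 px ≈ 150 nm at 0.1 µm/px, a diffraction-limited spot) whose
*integrated* intensity equals its level — the discrete kernel is
normalized to unit sum, so flux is conserved exactly and image intensity is
linear in levels. Constant background (default 20 a.u.) plus seeded
Gaussian read noise (default SD 3; Poisson available). No 3-D PSF,
photobleaching, or stage drift is modeled; synthetic movies are
motion-free by construction.

**Release trials and movies.** Release is independent Bernoulli(Pr) per AZ
per stimulus; event coordinates get isotropic Gaussian jitter (default SD
1 px) standing in for postsynaptic indicator localization error. Movies
place a Gaussian flash at each event on its stimulus frame, decaying
geometrically (default ratio 0.5 over 3 frames) over a baseline of
quiescent frames, at 15.3 frames/s.

**Paired perturbations.** `after = T(before) · (1 + cv·ξ) · drift + floor·ζ`
with T the null/additive/multiplicative transform, ξ, ζ standard normal.
The vehicle group shares drift and noise but not the transform, and comes
from an independent AZ map (different animals); if no vehicle map is
supplied its baselines are resampled from the treated map. The additive
noise floor (default 0, i.e. the pure-CV model) exists because an
intensity-independent measurement floor is what makes apparent decreases
concentrate among dim AZs — with purely proportional noise the decrease
rate is uniform across baseline terciles.

**Transients and ephys.** Ratio transients are instantaneous-rise
exponentials `ΔR·exp(−t/τ)` per 1 Hz action potential, a flat train
plateau, and noise entering through the Ca²⁺-sensitive channel; stimulus
times are snapped to the sample grid (114 Hz default) so noiseless peaks
are exact. mEJP amplitudes are gamma with stated mean/CV; each EJP sums a
Poisson(quantal content) number of quanta (floored at one).

What passing tests on these simulations do *not* show: robustness to
motion, focal drift, bleaching, non-Gaussian PSFs, spatially structured
background, multi-vesicular release, or GluR saturation — none of which
the generator emulates.

## Punctum detection

The chain is background subtraction → Gaussian filter (σ = 0.75 px) →
threshold → prominence-based maxima → marker watershed → measurement.

- **Background**: rolling-ball-equivalent grey morphological opening
  (disk radius 15 px) by default for structured background; a
  constant-offset mode (value estimated robustly from the image when not
  given) suits flat-background images. Subtraction clips at zero.
- **Threshold** (`min_intensity`): background mean + 2 SD. Background
  statistics are estimated on the *unclipped* smoothed image (pixels
  within 3 scaled MADs of the median), because estimating after
  zero-clipping halves the apparent noise and produces thresholds that are
  too permissive.
- **Noise tolerance**: flood-fill prominence — starting from the highest
  peak, the region reachable without descending more than the tolerance is
  claimed; any lower peak inside a claimed region merges into it. Default
  5× the smoothed-image background SD, calibrated on the synthetic suite;
  the acceptance-level detection results are insensitive to ±50 % changes
  around the default. Plateau maxima report the lexicographically smallest
  (y, x) pixel.
- **Segmentation**: marker-based watershed over the thresholded set;
  above-threshold pixels left in marker-free basins are assigned to the
  nearest maximum so labels exactly partition the thresholded set.
- **Measurement**: mean/sum intensities on the unfiltered
  background-subtracted image; centroids intensity-weighted on the
  smoothed detection image, so coordinates are identical for every
  mask-transfer target and substantially less noise-sensitive. Mask
  transfer applies one channel's label geometry to any number of
  co-registered targets, giving 1:1 punctum correspondence.
- Axon/non-synaptic removal is an optional boolean exclusion mask; Z-stacks
  are expected to be maximum-intensity projected before entry.

## Release mapping

Event detection subtracts a baseline image (mean of pre-stimulus frames),
then takes above-threshold local maxima in each stimulus frame; a peak
counts only if a maximum persists within a match radius (3 px) for at
least `persistence` (default 2) subsequent frames with non-increasing
amplitude (25 % slack for noise) staying above 5 % of the initial
amplitude — transient single-frame noise never qualifies. Coordinates are
the thresholded-maximum pixel; no sub-pixel fit. A preset
(`preset_live_tagrfp`: Gaussian σ = 2 + unsharp mask radius 3, weight 0.8)
prepares live punctum images for masking.

Assignment is pure nearest-centroid Euclidean distance (ties to the lowest
punctum id); an optional maximum radius flags far-field events unassigned,
off by default since the assay itself uses unrestricted nearest-neighbor
mapping. Within one stimulus, multiple events mapping to one punctum
collapse to a single release — Pr is per-stimulus binary — and
`Pr = distinct-stimulus count / n_stimuli` with n taken from the stimulus
log. Clopper–Pearson intervals quantify the binomial uncertainty.
Correlations are per-NMJ Pearson r between sum intensity and estimated Pr
(≥ 3 AZs and nonzero variance required; offending NMJs are excluded and
reported), averaged unweighted across NMJs.

## Plasticity analyses

- **Vehicle correction** divides treated after-values by the mean
  after/before ratio of the vehicle group — multiplicative, because the
  dominant session effects (drift, bleaching) scale intensities. It
  exactly inverts the generator's drift in the noise-free limit.
- **Paired test**: D'Agostino–Pearson normality gate on the deltas selects
  a paired t test or Wilcoxon signed-rank; all-zero deltas return p = 1.
- **Scaling fit**: additive and multiplicative candidates have one
  parameter each (closed forms `c = mean Δ`, `m = Σxy/Σx²`), so raw RSS
  comparison is a fair selection; AIC is reported for transparency, and
  fits within 5 % relative RSS (or both exact) are declared
  indistinguishable. The free OLS line carries an HC3
  heteroscedasticity-robust 95 % slope CI, since intensity noise scales
  with intensity and homoscedastic errors understate slope variance.
  Corrected after-values are the default y-axis (raw supported).
- **Terciles** are by baseline rank (stable ties), sizes within one of
  each other; "no change or decrease" is Δ ≤ 0 after correction; all three
  pairwise comparisons use two-sided Fisher exact tests.
- **Population comparisons** normalize per-NMJ means to the control-group
  mean and gate Student / Welch / Mann–Whitney on normality (Shapiro below
  n = 8) and a Levene variance check.

## Ephys

Quantal content is the per-recording ratio of mean EJP to mean mEJP,
averaged across recordings (mean of ratios — not the ratio of group means,
which differs whenever quantal size varies between recordings). Quality
gates: Vrest ∈ [−80, −60] mV, Rin ≥ 5 MΩ, ≥ 100 mEJPs, ≥ 20 EJPs. Raw
voltage-trace event detection is out of scope; the module consumes
amplitude lists.

## Transients

R(t) = rhod/AF647 (scale-invariant in loading); stimulus-aligned windows
averaged pointwise, sweeps overlapping the train excluded with a warning.
ΔR = peak − pre-stimulus baseline mean; τ from a nonlinear least-squares
fit of `A·exp(−t/τ) + B` from the peak onward (offset B because the window
may not reach baseline), initialized at the 1/e crossing time; fit failure
or τ ≤ 0 is an error. Train plateau = mean R over the last 50 % of the
train window minus baseline (the averaging window is a choice; the
fraction is configurable). Outlier exclusion uses the literal unscaled
3×MAD rule (median ± 3·median(|x − median|), inclusive bounds; the 1.4826
consistency factor is available as an option); zero MAD keeps only the
median with a warning. QC passes iff τ < 250 ms, strictly. The MAD rule is
applied per NMJ group of resting ratios by convention here; a per-bouton
grouping is a caller choice since the filter takes a plain value array.

## Pipeline, IO, determinism

TIFF IO is 16-bit grayscale (8-bit promoted with a flag; RGB and other
depths rejected; truncated files raise an error naming the failing page).
Tables are CSV keyed by `punctum_id` throughout, fits and reports JSON,
configuration YAML with unknown keys rejected; every run writes its
resolved config and a provenance record (stage parameters, seed, version,
in/out counts). All randomness flows through `numpy.random.default_rng`
seeded from the single run seed via `SeedSequence`, so identical seeds give
bit-identical tables.

## Problem sizes used in validation

The test suite validates at desk scale, chosen to keep the statistical
assertions sharp: 50 seeded 256×256 images of 100 AZs for detection; 1000
seeds × 100 AZs × 100 stimuli for Pr bias/coverage; 100 seeds for
correlation recovery (coupling noise 0.07, where the ground-truth-count
correlation is ≈ 0.8); 100 replicates per truth mode at n = 500 AZs for
scaling discrimination; 200 seeded transients for τ recovery; and full
enumeration of every 2×2 table with n ≤ 40 for Fisher exactness.

## Known limitations

- The Pr–intensity coupling form (affine in normalized level) and the
  noise-floor model are modeling choices, not measurements.
- Event detection assumes motion-free movies and isolated flashes; closely
  spaced simultaneous events within the match radius merge.
- The tercile analysis inherits whatever censoring the detection step
  imposes on dim puncta.
- No multi-vesicular release: Pr is strictly per-stimulus binary.
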