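# Methods

## Calcium-trace pipeline

### Model and procedure

Each ROI trace is raw fluorescence F(t) at a fixed frame interval (default
1/30.33 Hz ≈ 32.97 ms; acquisition software sometimes prints this as a
rounded "32 ms" interval — the frame rate is the configurable source of
truth). The pipeline is, per ROI:

1. **Baseline** `F0(t)`: mean of the lowest `ceil(fraction·k)` of the `k`
   samples in the causal window `(t − 30 s, t]`, `fraction = 0.5`. For
   t < 30 s the window expands from the first frame, so `F0(0) = F(0)`.
2. **dF/F0** = (F − F0)/F0; any `F0 ≤ 0` is a hard error naming the frame.
3. **Smoothing**: centered moving average over `round(0.8 s / dt)` frames,
   forced odd; edges use the available sub-window.
4. **Peak detection**: local maxima kept iff width at half prominence
   > 0.8 s, and value and prominence both > `sd(smoothed)/sensitivity1`
   with `sensitivity1 = 0.2`. "Width" is width at half prominence — the
   standard definition in peak-finding practice. The sd is the sample
   standard deviation (ddof = 1) of the ROI's whole smoothed dF/F0 curve,
   the most literal reading of "standard deviation of the measurement
   curve"; a noise-robust estimate would behave differently on active
   traces (see *Validity domain*).
5. **Artifact rejection**: for each candidate at frame f in ROI r, `AVGo`
   and `STDo` are the mean and sample sd of |smoothed dF/F0| of all other
   ROIs at f; the candidate is rejected iff its amplitude is below
   `(AVGo + STDo)/sensitivity2`, `sensitivity2 = 0.15`. The comparison uses
   smoothed dF/F0 rather than raw fluorescence because raw gains are not
   commensurate across ROIs. With a single-ROI field the statistic is
   undefined; candidates are kept and a warning emitted.
6. **Kinetics** on accepted peaks: rise = last upward crossing of 10% of the
   peak value before the peak → peak; decay = peak → first downward
   crossing after it; crossings by linear interpolation between frames;
   duration = rise + decay. A side whose crossing lies outside the recording
   or beyond the adjacent accepted peak of the same ROI is censored (NaN),
   and the duration with it. "Duration" is reported as the 10% → 10% span
   because no other definition is standard for these slow transients.
7. **Summaries**: per timepoint group and ROI kind (soma/neurite), the
   proportion of ROIs with ≥ 1 accepted event, plus tidy per-event vectors
   (amplitude, duration, rise, decay) ready for external statistics.

Both the peak value and the prominence are emitted per event; "amplitude"
refers to the peak's smoothed dF/F0 value.

### Validity domain

Three properties of the procedure bound where its outputs are quantitative;
they are inherent to the method, not implementation choices:

* **Percentile-baseline bias.** `F0` is the mean of the lowest half of the
  window, so it underestimates the true baseline by ≈ 0.8·σ_noise, and any
  *negative* deflection inside the window (movement artifact) drags it
  further down, inflating every amplitude measured in the following 30 s
  roughly in proportion to the artifact duty cycle. The method is accurate
  when noise is a small fraction of the baseline and artifacts occupy a few
  percent of any window.
* **Whole-curve sd threshold.** The detection threshold is
  `sd(curve)/0.2 = 5·sd`. A 330 s trace containing one amplitude-A
  transient (integrated-square width ≈ 5.3 s for the default kernel) has
  `5·sd ≈ 0.64·A`; with two such transients ≈ 0.90·A. Traces with zero to
  two prominent peaks are the regime in which the fixed sensitivities are
  meaningful; on busier or shorter traces the threshold saturates toward
  the amplitude itself.
* **Consensus filter vs. synchrony.** Anything simultaneous across the
  field is rejected — including genuinely co-active cells whose peaks align
  within a few seconds. This is the intended trade-off of the artifact
  filter.

The recovery tests therefore score *isolated* transients (peak after the
first full baseline window, single-event trace, no cross-ROI peak within
5 s, no artifact on the transient's span or — with negative sign in that
ROI — in its preceding baseline window); every injected artifact outside the
warm-up period is scored for rejection. Passing these tests shows the
implementation reproduces the procedure faithfully inside its domain; it
does not certify behaviour on data that violate the conditions above.

## Synthetic trace generator

`F(t) = B·(1 + drift) + Σ_events A·B·g(t − t0) + artifacts + noise`, floored
at a small positive background (detector offset plus neuropil; a real
recording never reaches zero even when movement drives the ROI off the
cell). The transient kernel is the unit-peak double exponential
`g(t) ∝ (1 − e^(−t/τr))·e^(−t/τd)` — the standard indicator model, chosen
because it is analytically invertible (peak time `τr·ln((τr+τd)/τr)`, 10%
crossings solvable) for ground-truth tests. Defaults, chosen once to mirror
the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_rois, n_frames, rate | 50, 10 000, 30.33 Hz | ~50 traces per movie, 330 s recordings |
| baseline B | 100 a.u. | arbitrary gain; detection is scale-invariant |
| drift | 2% slow sinusoid | slow focus/expression drift |
| noise sd | 0.3 a.u. (0.3% of B) | two-photon soma SNR regime |
| events/ROI | Poisson, mean 0.5 | "zero to two prominent peaks" per trace |
| amplitude | dF/F0 = 10 | the reported dendritic amplitude scale |
| τ_rise, τ_decay | 2 s, 5 s | rise ≈ 2.4 s, decay-to-10% ≈ 13 s: seconds-scale onset, slower descent |
| artifacts | 2/min, 1 s boxcar, per-ROI sign, sd 300 a.u. | ~11 per movie (reported range 10–50), dF/F ≈ ±3, "equally large and long"; duty cycle ~3%, inside the percentile-baseline validity domain |

Event onsets are placed so each transient completes its decay to 10% inside
the recording (a truncated decay lowers prominence and censors kinetics).
Artifacts are single-onset boxcar deflections shared by all ROIs with
per-ROI random sign and magnitude. Not emulated: photobleaching, optical
PSF, vascular shadowing, behavioural covariates, amplitude variability
across events.

## Histology quantification

* **z-grouping**: plain mean over groups of 4 planes (20 → 5), z-step
  scaled.
* **Graft ROI across z**: linear blending of the signed Euclidean distance
  transforms of the two hand-drawn end masks, thresholded at 0. For
  concentric disks this interpolates the radius linearly; it needs no
  vertex correspondence, which is undefined for hand-drawn polygons.
  Degenerate all-empty/all-full end masks use a large constant signed
  distance.
* **50 µm split**: `below50` = graft pixels whose Euclidean distance to the
  mouse-cortex mask is ≤ 50 µm (pixel-center sampling); `above50` the
  remainder; the partition is exact by construction. Everything outside the
  graft is mouse cortex; in the one-stack pipeline the cortex mask is the
  graft complement, which presumes the frame starts at the pial surface.
* **Thresholds**: Otsu by default (reproducible and parameter-free, and the
  resulting area fractions are invariant to uniform channel rescaling);
  per-channel fixed overrides for calibrated channels, e.g. the human-cell
  mask at green ≥ 5000. Fixed thresholds use ≥, Otsu the conventional >.
* **DAPI gating**: connected components of a marker mask that nowhere touch
  DAPI are removed whole; pixelwise AND would bisect nuclear rims.
* **Colocalization**: per z-plane and compartment, area(marker ∩ partner ∩
  compartment) in µm² with two normalizations — per total DAPI area and per
  partner (GFP/STEM101) area — then averaged across the working z planes.
  Both normalizations appear in the literature for these data and neither
  is canonical, so both are always emitted. Zero denominators yield missing
  values rather than zeros.

The stack simulator places nuclei as a spatial Poisson process in a flat
horizontal graft band over cortex (graft irregularity is irrelevant to the
quantification logic) and assigns markers per compartment probabilities
(defaults: Sox2 in 65% of graft vs 32% of cortical nuclei; GFP human-only).
GFP is rendered on the same disk footprint as the nuclear markers: the area
ratio "Sox2∩GFP / GFP" equals the cell-level probability only when numerator
and denominator share per-cell footprints, which is the quantity the
pipeline is meant to recover. With disk overlaps the boolean-model bias is
≈ +1–3 percentage points at the default ~10% coverage; recovery tests use
≥ 300 nuclei so binomial error (±2.5 points at 1σ) plus that bias stays
within ±5 points.

## Puncta, EM and spines

* **Spot detection** is single-scale difference-of-Gaussians (σ/√2 minus
  σ√2), local maxima above an absolute response `min_quality`, sub-pixel
  centers by per-axis quadratic interpolation. It replaces the wavelet spot
  detector of interactive suites and is validated against simulated truth
  instead of matched to any external tool. Two spots closer than ≈ 2σ merge
  — at 0.5 puncta/µm² and a diffraction-limited σ of 0.15 µm this costs
  ≈ 10% of counts (tested at ±15% with Poisson error); the generator's
  default densities (0.05–0.15/µm²) keep mean spacing several-fold above
  the limit. For thin z-stacks, spots on adjacent planes within one punctum
  radius merge into one count.
* **Densities**: spots whose center pixel lies in compartment ∩ human mask,
  divided by that intersection area (pixel count × pixel size²); zero area
  gives a missing value. The spot-in-region test uses the center only, not
  the spot extent. The puncta generator places `round(density × area)`
  spots uniformly (optional minimum separation; 1 px border margin so
  center-pixel membership is unambiguous), so requested counts are exact.
* **EM areal density**: `n/area × 100`, reported alongside its
  truncated-toward-zero integer — the convention that reproduces both
  published worked examples (12/258 → 4.65 → "4"; 53/258 → 20.54 → "20";
  conventional rounding would contradict the first). The raw value is
  always emitted.
* **Spine density**: per-dendrite count/length and their unweighted mean.

## Numerical conventions

Masks are raster, 0-based, row-major, pixel-center sampled; areas are pixel
counts × pixel_size². Baseline windows never go empty (expanding start);
moving-average windows are forced odd. Kinetic crossings are linearly
interpolated; censored values are NaN and propagate into durations. AVGo/STDo
use ddof = 1 with STDo = 0 when only one other ROI exists. All simulators are
deterministic given their seed (numpy `default_rng`).

## Known limitations

* The percentile baseline is biased low under heavy noise or dense
  artifacts; amplitudes are then overestimated (see *Validity domain*).
* The detection threshold saturates on traces with more than ~2 large
  transients; fixed sensitivities are not adaptive.
* The consensus filter cannot distinguish network-synchronous activity from
  movement.
* Colocalization area fractions are a proxy for cell fractions and inherit
  the boolean-overlap bias at high nuclear density; no instance
  segmentation is attempted.
* Spot detection is single-scale and undercounts at spacings near 2σ.
* Image simulations replicate one 2-D layout across z (no 3-D nuclear
  shapes, PSF or bleaching), so passing recovery tests demonstrates correct
  quantification logic, not robustness to real optics.
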