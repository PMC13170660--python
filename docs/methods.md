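# Methods

This note documents the models, defaults, and numerical conventions behind
iglonquant, and what the synthetic-data validation does and does not show.

## ΔF/F0 baseline

Raw per-ROI fluorescence F is normalized as ΔF/F0 = (F − F0)/F0.  F0 is a
scalar per ROI: the trace is tiled into consecutive non-overlapping windows
of `window_s` (default 60 s); F0 is the mean over windows of each window's
50th percentile.  A trailing partial window of at least half the nominal
length stands alone; a shorter remainder is merged into the previous window.
Percentiles use linear interpolation between order statistics, and the test
oracles use the same convention.  "Average of the 50th percentile across a
window" could also be read as a rolling, time-varying baseline; the tiled
scalar reading is implemented because it matches the phrase most literally,
and the contract (a positive F0 per ROI) would admit a rolling variant
without interface changes.  Frames with non-finite values are a hard error —
silent imputation would corrupt downstream event statistics.

The percentile baseline is exact whenever transients occupy fewer than half
the frames of every window; properties verified by tests include gain
invariance (ΔF/F0 of k·F equals that of F for any k > 0) and weak
monotonicity of F0 in the input.

## Transient detection

A library of difference-of-exponentials waveforms,
w(t) ∝ exp(−t/τ_decay) − exp(−t/τ_rise), peak-normalized to 1 on the
sampling grid, is built over the grid τ_rise ∈ {0.05, 0.1, 0.2} s ×
τ_decay ∈ {0.3, 0.6, 1.2} s with a 3-s template length — fast-indicator
(GCaMP6f-like) kinetics.  A window of template length slides along each
ΔF/F0 trace (windows must fit entirely inside the trace; no zero-padding).
The similarity score is the Pearson correlation between the mean-subtracted
window and each template; the window's score is the maximum over templates.
A position is a candidate when similarity ≥ 0.75 **and** the window's peak
ΔF/F0 ≥ 0.01 (the minimum amplitude is the observed peak in the window, not
a fitted coefficient).  Candidates are pruned by greedy non-maximum
suppression on similarity with a refractory distance of half the template
length between onsets, ties broken toward the earlier onset.  Pearson
correlation was chosen as the similarity metric because it is scale-free
and bounded in [−1, 1], making 0.75 a meaningful cut; on noiseless isolated
transients the decaying tail of an accepted event never re-crosses the
similarity threshold with this template grid, so the half-length refractory
window suffices.

Events are counted per ROI and converted to spikes/min = count/(duration/60);
ROIs without events are retained at rate 0.

## Hyperactivity classification

The threshold is computed per timepoint from the control group only:
mean + 2 × sample SD (ddof = 1; the small-sample convention).  A neuron is
*silent* at exactly 0 spikes/min, *hyperactive* strictly above the
threshold, and *active* otherwise — a rate exactly at threshold is active,
because hyperactivity is defined by "larger than".  "Inactive" and "silent"
name the same class.  A zero-variance control pool is permitted (threshold
collapses to the mean) but raises a warning.  Class fractions are computed
with exact rational arithmetic on counts, so they always sum to 1.0.
Group means can be normalized to any reference group/timepoint mean
(degenerate zero reference is an error).

Calibration: with treated rates drawn from the same Gaussian as controls
(300 per group), the median hyperactive fraction over 200 seeds sits at the
one-sided 2σ tail (~2.3%); with a 3× rate multiplier the treated fraction
exceeds the control's in every tested seed.

## Image statistics

**Missorting MFI.**  MFI = (RawIntDen_soma − RawIntDen_nucleus) /
(Area_soma − Area_nucleus), algebraically the pixelwise mean of the Tau
channel over soma AND NOT nucleus — both routes are computed in the tests
and agree to machine precision.  ROI masks are inputs (manual or
synthetic); there is no automatic soma segmentation, mirroring how the
assay is scored.  Intensities are used as-is (no background subtraction).

**Clusters.**  MAP2+ mask by a global Otsu threshold; cluster channel
Gaussian-smoothed (σ = 1 px default), Otsu-thresholded, intersected with
the MAP2+ mask, labeled with 8-connectivity; components under
`min_area_px` (default 2) are discarded.  Density = count / MAP2+ area
(per px², per µm² when a pixel size is supplied); radius is the
equivalent-circle radius √(area/π).  The exact segmentation recipe of the
original interactive pipeline is unpublished, so correctness is defined
against synthetic ground truth (exact count/density recovery for 0–20
puncta), not parity with any specific tool.  A constant-positive channel
thresholds to all-foreground (Otsu needs two grey levels).

**Nuclei and tangles.**  Nuclei: global threshold + connected components +
size filter (default 20 px).  Touching nuclei merge into one component —
a documented limitation (no watershed).  Tangle fraction =
100 × # tangles / # DAPI+ nuclei, with tangles ≤ nuclei enforced.

## One-site binding

MFI(c) = MFI_max·c/(Kd + c), fitted by unweighted nonlinear least squares
(`scipy.optimize.curve_fit`, positive-parameter bounds).  Initialization:
MFI_max₀ = max observed MFI, Kd₀ = the concentration nearest half-max, plus
five log-spaced Kd starts spanning 0.1×–10× the dose range; the lowest-RSS
solution wins.  Standard errors come from the covariance of the best fit;
non-convergence across all starts is flagged and parameters are withheld.
The published formula substitutes 0.5·MFI_max for Kd, which puts a
fluorescence quantity in a concentration slot; the free-Kd form is the
default (consistent with "one site-specific binding"), and the literal
variant is available as `variant="half_max_of_mfimax"` for reproduction.
The fit accepts per-image means or per-neuron values alike; replicates are
simply stacked observations.  Mass-to-molar conversion uses
nM = 10⁶·(g/L)/(g/mol) with a 150-kDa default IgG mass.

## Synthetic data

The generators emulate the study's acquisition regimes and are the ground
truth for all recovery tests:

* **Spikes** — homogeneous Poisson per neuron; population heterogeneity is
  log-normal in rate (parameterized by its arithmetic mean; shape σ = 0.5
  default).  The readout of record is a population spike-rate summary, so
  the simplest rate model carrying that statistic was chosen; defaults are
  free parameters, not claims about real cultures.  Default mean rate
  2 spikes/min.
* **Fluorescence** — F(t) = baseline_F·exp(−bleach·t)·(1 + Σ kernel
  responses) + additive Gaussian noise; linear superposition; spike times
  quantized to the 8-Hz grid.  Kernel defaults: rise 0.1 s, decay 0.6 s,
  amplitude 0.5 ΔF/F0, peak-normalized on the grid so the rendered peak
  equals the amplitude exactly.  Default acquisition 180 s at 8 Hz
  (frames = ⌊duration·fs⌋); default noise 2 a.u. on a baseline of 100
  (≈ 0.02 ΔF/F0).  No shot noise or calcium-buffering biophysics — the
  noise model is sufficient to stress the percentile baseline, not a
  camera model.
* **Populations** — each neuron draws one base rate; per-timepoint
  multipliers scale it (paired before/after design, matching recordings of
  the same cultures at 0 and 60 min), so a multiplier of 3 triples a
  group's true mean rate exactly.
* **Images** — circular nucleus strictly inside a circular soma with
  straight neurites; a fraction `allocation_somatic` of the Tau amplitude
  goes to the cytoplasm, the remainder to neurites; puncta are disjoint
  disks on dendrite bands with a minimum separation (6 px default) chosen
  so segmentation smoothing cannot merge them.  Each fixture stores truth
  recomputed from its own noiseless rendering by the matching
  quantification routine, making noise-free round trips exact by
  construction.
* **Binding** — responses on the 0.01/0.1/1/10 µg/ml grid with
  multiplicative Gaussian noise of coefficient `noise_cv`.

Every generator is a pure function of (parameters, seed); a run-level
master seed derives per-operation seeds via `SeedSequence` over a label
hash.  What passing tests show is that the pipeline recovers known truth
under these idealized conditions (isolated transients, Gaussian noise,
disjoint puncta, manual-quality masks); they do not certify performance on
real recordings with overlapping events, neuropil contamination, motion,
or touching cells.

## Problem sizes

Validation runs use 100-neuron recordings for detection scores, 200 seeds ×
300 neurons/group for the null calibration, 100 seeds × 40 neurons/group
for effect sensitivity, 50 random geometries for the missorting oracle,
0–20 puncta for cluster recovery, and 100 seeds for noisy Kd recovery —
sizes at which the Monte-Carlo bounds asserted by the tests are stable
across seeds.

## Interfaces

Trace CSV: `time_s` column plus one column per ROI.  Images: multi-page
float32 TIFF with a JSON manifest mapping channel role → page.  ROI masks:
2-page TIFF (soma, nucleus) or polygon JSON.  Configs: TOML, validated by
pydantic at load, exact read→write→read round trip.  The CLI exposes each
stage as a subcommand; all stochastic subcommands accept `--seed` and are
byte-deterministic under a fixed seed.
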