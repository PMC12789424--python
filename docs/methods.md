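# Methods

This note documents the models and procedures implemented in
`spherotrack`, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## The assay

A neural spheroid (a self-aggregated cluster of iPSC-derived cortical
neurons, ~350 µm across) adheres to a laminin-coated plate and extends
radial axons. Glioblastoma (GB) cells seeded nearby migrate along
those axons — contact guidance — and infiltrate the spheroid. Two
readouts quantify this:

1. **Live tracking**: time-lapse imaging of the field beside the
   spheroid yields one (x, y) trajectory per cell, sampled every
   15 min over 24 h. The spheroid sits in the +x direction, so guided
   migration shows up as horizontal anisotropy of net displacement.
2. **Endpoint imaging**: daily two-channel confocal z-stacks
   (channel 1 = spheroid nuclear dye, channel 2 = GB cytoplasmic dye)
   are reduced to "labelled cells inside the spheroid ROI" counts.

## Track reduction and directionality

Tracks require ≥ 2 points, strictly increasing frames and times;
rows with missing coordinates and sub-minimal tracks are dropped with
logged counts. Per-step instantaneous velocity is
‖pᵢ₊₁ − pᵢ‖/(tᵢ₊₁ − tᵢ); mean speed is path length over elapsed time,
so mean speed × elapsed time ≥ ‖net displacement‖ always (chord ≤
path). The net angle θ = atan2(Δy, Δx) lies in (−180°, 180°] with ties
at ±180° folded to +180°, keeping the anti-spheroid direction
unambiguous. Trackers exporting row-major image coordinates can be
read with `image_rows=True`, which negates y; otherwise angle signs
would flip.

The polar histogram uses bins of width 360°/n with edges at ±180°/n so
one bin is centred exactly on 0°; n = 36 (10° bins) by default, making
the isotropic expectation 2.78% per bin.

**HPI.** The Horizontal Preference Index is magnitude-weighted
net-displacement anisotropy,

    HPI = Σᵢ(|Δxᵢ| − |Δyᵢ|) / Σᵢ(|Δxᵢ| + |Δyᵢ|),

over per-track net displacements, ignoring stationary tracks. Chosen
properties: bounded in [−1, 1] with the extremes attained by purely
horizontal/vertical motion; expectation 0 under isotropy (E|Δx| =
E|Δy| by symmetry); scale-invariant; negated by 90° rotation or
reflection across y = x. A per-step pooled variant
(`per_step=True`) weights long tracks by their activity rather than
their net drift. Bootstrap confidence intervals resample tracks with
replacement (percentile, 1000 reps, seeded).

**Uniformity tests.** The Rayleigh test uses R̄ = |Σe^{iθ}|/n,
Z = nR̄², with the standard first-order corrected approximation
p ≈ e^{−Z}[1 + (2Z − Z²)/(4n)] clamped to [0, 1]; it agrees with the
alternative large-sample approximation to < 0.5% at moderate Z and is
calibrated to 4–6% rejections at α = 0.05 under uniformity (verified
over 2000 replicates of n = 100). The χ² test bins angles with the
same 0°-centred bins and warns when expected counts drop below 5;
callers should reduce `n_bins` (8 bins for n = 100) accordingly.

## Endpoint imaging pipeline

All segmentation operates on the pixel-wise **maximum projection**
across z, mirroring standard high-content practice; no 3-D
segmentation is attempted.

**Spheroid ROI**: global threshold (Otsu by default, fixed threshold
available), morphological closing (disk radius 3 px), hole filling,
largest connected component. A minimum-area guard (default
1000 µm²) turns threshold artifacts into an explicit empty-ROI error.

**Cell detection**: Gaussian pre-smoothing at σ = 1.5 px (a matched
filter for ~2 px spots — without it, noise maxima surviving the
z-projection become false positives at low SNR), white top-hat with
radius 8 px (larger than a cell) to flatten background, Otsu threshold
floored at 6 robust (MAD-based) noise SDs so a pure-noise image yields
zero detections, connected components filtered to [20, 150] µm², and
distance-transform watershed splitting of oversized components with
peaks at least half a cell diameter apart. Centroids are
intensity-weighted and converted to µm as pixel-centre × pixel size
(0-based indices).

**Counting**: a detected cell infiltrates if its centroid pixel lies
inside the ROI mask — the simplest rule consistent with counting
"cells in the ROI". On noise-free synthetic stacks this recovers the
configured inside-count exactly across (0..20) × (0..40)
inside/outside combinations; at signal-to-noise 5 it was exact in
200/200 seeded stacks. The documented SNR floor for both segmentation
(IoU ≥ 0.95) and exact counting is SNR 5 with the default geometry.

**Shape metrics**: area (pixel count × pixel size²),
equivalent-circle diameter √(4A/π), maximum Feret diameter, aspect
ratio AR = major/minor of the second-moment ellipse, roundness =
4A/(π·major²). For exact ellipse masks roundness × AR = 1, which makes
the two printed spheroid summaries (roundness 0.97, AR 1.03;
product 0.999) mutually consistent under these moment-ellipse
definitions. The published mean diameter (~351 µm) and published area
(~82,000 µm² ⇒ equivalent diameter ~323 µm) disagree; since the
measure behind the published "diameter" is not recoverable, both
equivalent-circle and Feret diameters are reported and neither is
asserted as that value.

## Infiltration statistics

**Baseline correction** subtracts each well's day-0 raw count from all
its days (error if day 0 is absent); negatives are retained so the
data remain faithful, and are floored at 0 only inside the
log₁₀(y + 1) transform, with the flooring count logged.

**Z-factor**: Z = 1 − 3(σ₊ + σ₋)/|µ₊ − µ₋| per day for a (positive =
invasive, negative = control) pair; the assay window is the argmax day
(ties to the earliest), flagging days with Z ≥ 0.5 as excellent by the
usual screening convention. Evaluating the formula on the published
day-3 summaries (9.9 ± 0.6 vs 3.0 ± 0.2 cells) gives 0.652, which this
package reports for that pair.

**Time-course test**: two-way repeated-measures ANOVA on
log₁₀(y + 1)-transformed corrected counts — condition between
subjects (each well carries one cell line), day within (wells are
re-imaged daily) — delegated to `pingouin.mixed_anova`. The
Geisser–Greenhouse epsilon of the within factor is applied to both the
day main effect and the condition × day interaction (the interaction
shares the within-subject error term). Unbalanced designs raise an
error listing the missing (well, day) cells. Pairwise condition
contrasts per day are Tukey-adjusted; day 0, identically zero after
baseline correction, is skipped. Under pure-null simulation (200
replicates, 3 conditions × 3 wells × 4 days, σ = 1) the GG-corrected
tests rejected at 4.5% (condition) and 2% (interaction) at α = 0.05 —
conservative, as expected from the correction.

**Screen test**: per cell line at the readout day, a Kruskal–Wallis
omnibus across vehicle + compounds, then Dunn's rank-based z
comparisons against vehicle with tie correction, family-wise adjusted
over the compounds-vs-vehicle family (Holm by default; the method is
recorded in the output). Under null simulation (1000 replicates) the
family-wise false-positive rate was 5.2% at α = 0.05; an 80%
infiltration reduction at n = 6 replicates was detected in 100% of 200
seeded replicates.

**Morphology counter-screen**: per-group mean ± SD of cellular
roundness and width-to-length ratio (= 1/AR), with differences vs the
control group, to rule out cytotoxic shape collapse as the cause of
reduced infiltration.

## Synthetic-data generators

All three generators are deterministic given their seed (bit-identical
outputs) and export full ground truth.

**Tracks** follow a biased persistent random walk: the heading evolves
by wrapped-normal perturbation of the previous heading with circular
SD 1/√κ (default κ = 4, ≈ 29° per 15-min step — a moderately
persistent mesenchymal walk); with probability w (guidance weight)
a step's heading is instead re-anchored on the horizontal axis (0°
with probability p, else 180°) plus the same noise. Speeds are drawn
per step from a truncated normal (default 0.5 ± 0.15 µm/min, floored
at 0), positions advance by speed × dt. Defaults: 1000 cells, 97
frames at 15 min (24 h), starting positions uniform over a 2 × 2 mm
field. w = 0 reproduces isotropy (HPI ≈ 0, uniformity tests at
nominal level); HPI rises monotonically with w. The published assays
report no speed or persistence values for any line, so these defaults
are plausible magnitudes for glioma cells on a 2-D substrate, not
claims about particular lines; guidance lives in the track statistics
only — no axon imagery is simulated.

**Image stacks**: channel 1 renders the spheroid as a filled disc
(default radius 175.5 µm, the published mean diameter) with a smooth
cosine axial intensity profile across 10 planes at 2 µm spacing;
channel 2 renders each cell as an isotropic Gaussian spot (σ = 2 px)
concentrated in one random plane with 40% bleed into neighbours.
Cell centroids are rejection-sampled uniformly inside/outside the disc
with ≥ 5σ mutual separation (configured spots are resolvable — the
deliberately touching pair used to test watershed splitting is
constructed directly) and a 5 px clearance from the disc edge so
inside/outside labels are unambiguous. Noise is additive Gaussian at
peak-signal-to-noise `snr` (default 10), or Poisson with ≈ snr² peak
photons, or none. Not modelled: PSF blur beyond the Gaussian spot,
depth attenuation, autofluorescence, or cells overlapping the spheroid
rim — so passing tests demonstrate the pipeline's correctness on
resolvable objects, not its robustness to dense clumping inside a real
spheroid core.

**Plate counts**: expected raw count = baseline + compound effect ×
cumulative per-day growth; observed = expected + integer-rounded
Gaussian noise, floored at 0 (so zero-noise tables equal the
configured means exactly). Default growth increments reproduce the
published baseline-corrected trajectory shape — control rising to ~3
cells and the two GB lines to ~10 and ~6.4 by day 3 — with unprinted
days interpolated; default noise SD 0.8 matches the spread of the
published replicate SDs (0.2–1.6). Replicates model independent
experiment means (technical wells pre-averaged), which is why the
examples use smaller noise when illustrating Z-factor windowing.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: 500–1000
tracks per condition, 2000 calibration replicates, 200-stack counting
campaigns on 384² × 10 canvases, and a 36-stack end-to-end time course
on 256² × 6 canvases — sizes at which every Monte-Carlo tolerance
stated in the tests (3 binomial SEs unless noted) is meaningful.
Angle ties at bin edges go to the higher bin; Otsu on a constant image
is an explicit error; Z-factor with equal means is an explicit error
rather than ±∞; the Rayleigh p is clamped to [0, 1].

## Known limitations

* The published HPI values (+0.27…+0.34 with axons) derive from a
  single experiment's proprietary tracker exports with an unstated HPI
  formula and bin count; they are qualitatively, not numerically,
  reproducible. The implemented HPI matches every stated property
  (sign, zero under isotropy, bounds).
* The published Z-factor 0.701 cannot be recomputed from the published
  day-3 summaries (the formula gives 0.652 for the invasive-vs-control
  pair); the package reports per-pair Z-factors and does not target
  0.701.
* The infiltration metric counts labelled cells; it does not separate
  migration from proliferation, exactly as in the source assay.
* The RM-ANOVA assumes a complete balanced design; wells lost during
  an experiment must be dropped or imputed upstream.
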