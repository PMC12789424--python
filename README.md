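# spherotrack

Quantitative analysis of glioblastoma (GB) infiltration into
iPSC-derived neural spheroids.

In axon-guided co-culture assays, patient-derived GB cells migrate
along neurites radiating from a neural spheroid and eventually invade
the spheroid itself. `spherotrack` implements the complete downstream
analysis for such assays:

* **Migration-track directionality** — per-track motility metrics
  (instantaneous velocity, mean speed, net displacement), polar
  histograms of net migration angles, and the **Horizontal Preference
  Index**

  `HPI = Σᵢ (|Δxᵢ| − |Δyᵢ|) / Σᵢ (|Δxᵢ| + |Δyᵢ|)`

  over per-track net displacements — 0 in expectation for isotropic
  migration, +1 when all net motion is horizontal (along the
  axon/spheroid axis), −1 when vertical — plus Rayleigh
  (`Z = nR̄²`) and χ² tests of circular uniformity.
* **Endpoint image analysis** — maximum projection of two-channel
  z-stacks, Otsu segmentation of the spheroid ROI, matched-filter +
  top-hat + watershed detection of labelled cells, centroid-in-ROI
  infiltration counting, and moment-ellipse shape metrics
  (area, diameters, aspect ratio AR = major/minor,
  roundness = 4·area/(π·major²)).
* **Infiltration statistics** — per-well baseline correction, mean ± SD
  summaries, CV%, the Z-factor assay-quality statistic
  `Z = 1 − 3(σ₊ + σ₋)/|µ₊ − µ₋|` with per-day assay windowing,
  two-way repeated-measures ANOVA with Geisser–Greenhouse correction on
  log₁₀(y+1) counts, and Kruskal–Wallis + Dunn drug-screen testing.
* **Synthetic data** — seeded generators (biased persistent random
  walks, two-channel spheroid image stacks, plate count tables) with
  exported ground truth, so every stage is testable end to end.

## Worked example

```python
import numpy as np
import spherotrack as st

# ~1000 cells imaged every 15 min for 24 h, with contact guidance
cfg = st.SimulationConfig(seed=1, n_cells=1000, n_frames=97,
                          guidance_weight=0.6, drift_toward_spheroid=0.7)
metrics = st.metrics_table(st.tracks_from_table(st.simulate_tracks(cfg)))
hpi = st.compute_hpi(np.column_stack((metrics.net_dx, metrics.net_dy)),
                     n_boot=500, seed=0)
print(f"HPI = {hpi.hpi:+.3f} [{hpi.ci_low:+.3f}, {hpi.ci_high:+.3f}]")
```

prints

```
HPI = +0.678 [+0.665, +0.691]
```

a strong horizontal preference (the matching isotropic simulation gives
`HPI = -0.026 [-0.054, +0.007]`, a confidence interval covering 0).
The `examples/` scripts walk through each capability — directionality,
endpoint counting (e.g. `infiltrating (inside ROI): 12 (ground truth
12)` at signal-to-noise 5), Z-factor assay windowing, and the drug
screen — each printing the numbers it computes and what they mean.

A thin CLI mirrors the library for batch work
(`spherotrack simulate-tracks | analyze-tracks | simulate-images |
analyze-endpoint | simulate-screen | analyze-timecourse | screen |
report`); every run writes a JSON manifest with the seed, parameters
and input hashes so artifacts are reproducible byte for byte.

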