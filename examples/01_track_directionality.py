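"""Directionality of simulated migration tracks.

Simulates two cohorts of cells — one migrating isotropically (no
axons) and one with contact guidance along the horizontal axis (axons
present) — and summarises each with the Horizontal Preference Index
(HPI), the 0-degree polar-bin occupancy, and the Rayleigh uniformity
test.  Under guidance the HPI turns positive, the bin facing the
spheroid fills beyond the isotropic 2.8%, and the Rayleigh p collapses.
"""

import numpy as np

import spherotrack as st

for label, w, p in (("no axons", 0.0, 0.5), ("axons", 0.6, 0.7)):
    cfg = st.SimulationConfig(
        seed=1, n_cells=1000, n_frames=97,
        guidance_weight=w, drift_toward_spheroid=p, condition=label,
    )
    tracks = st.tracks_from_table(st.simulate_tracks(cfg))
    metrics = st.metrics_table(tracks)
    angles = metrics.net_angle.dropna().to_numpy()

    hpi = st.compute_hpi(
        np.column_stack((metrics.net_dx, metrics.net_dy)), n_boot=500, seed=0
    )
    hist = st.polar_histogram(angles, n_bins=36)
    central = hist.percentages[np.where(hist.bin_centers == 0.0)[0][0]]
    rbar, z, p_ray = st.rayleigh_test(angles)

    print(f"{label:9s}  HPI = {hpi.hpi:+.3f} "
          f"[{hpi.ci_low:+.3f}, {hpi.ci_high:+.3f}]  "
          f"0-deg bin = {central:4.1f}%  Rayleigh p = {p_ray:.2e}")

print(
    "\nHPI > 0 with a filled 0-degree bin means cells preferentially move\n"
    "along the horizontal axon axis toward the spheroid; the isotropic\n"
    "cohort stays near HPI = 0 with ~2.8% per bin."
)
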