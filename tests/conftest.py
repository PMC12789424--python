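import numpy as np
import pandas as pd
import pytest

from spherotrack import (
    ImageSynthesisConfig,
    SimulationConfig,
    synthesize_stack,
)


@pytest.fixture(scope="session")
def two_track_table() -> pd.DataFrame:
    """A minimal well-formed track table with two tracks."""
    rows = []
    for tid, pts in {
        "t1": [(0, 0.0, 0.0, 0.0), (1, 15.0, 3.0, 4.0), (2, 30.0, 6.0, 8.0)],
        "t2": [(0, 0.0, 10.0, 10.0), (1, 15.0, 12.0, 10.0)],
    }.items():
        for frame, t, x, y in pts:
            rows.append(
                {
                    "track_id": tid,
                    "frame": frame,
                    "time_min": t,
                    "x_um": x,
                    "y_um": y,
                    "condition": "ctrl",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def endpoint_fixture():
    """A clean two-channel stack with 12 cells inside / 30 outside."""
    cfg = ImageSynthesisConfig(
        seed=202, n_cells_inside=12, n_cells_outside=30, snr=10.0
    )
    stack, truth = synthesize_stack(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def isotropic_tracks():
    """1000 isotropic simulated tracks (guidance weight 0)."""
    from spherotrack import simulate_tracks

    cfg = SimulationConfig(seed=31, n_cells=1000, n_frames=49, guidance_weight=0.0)
    return simulate_tracks(cfg)


def true_disc_mask(cfg: ImageSynthesisConfig) -> np.ndarray:
    rows, cols, _ = cfg.canvas
    cr, cc = cfg.center_px()
    r_px = cfg.spheroid_radius / cfg.pixel_size
    yy, xx = np.mgrid[0:rows, 0:cols]
    return ((yy - cr) ** 2 + (xx - cc) ** 2) <= r_px**2
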