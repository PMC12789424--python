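"""Synthetic data generators with known ground truth.

Three generators stand in for the raw data of a neural-spheroid /
glioblastoma co-culture infiltration assay:

* :func:`simulate_tracks` — single-cell migration tracks following a
  biased persistent random walk.  A guidance weight ``w`` mixes an
  isotropic persistent walk with alignment to the horizontal axis, the
  direction in which axons extend from the spheroid toward the imaged
  field.  ``w = 0`` gives isotropic motility; ``w = 1`` gives fully
  axon-guided motility.
* :func:`synthesize_stack` — two-channel z-stacks of a labelled spheroid
  (channel 1, a filled disc) and labelled invading cells (channel 2,
  Gaussian spots), together with a ground-truth centroid table.
* :func:`simulate_screen_counts` — plate-level infiltrated-cell counts
  across conditions, compounds and days for screen statistics.

All generators are deterministic given their ``seed``: the same config
produces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "ImageSynthesisConfig",
    "ScreenSimConfig",
    "ConfigError",
    "simulate_tracks",
    "synthesize_stack",
    "simulate_screen_counts",
]


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Track simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the biased persistent random walk.

    Parameters
    ----------
    seed
        Random seed; identical seeds give bit-identical track tables.
    n_cells, n_frames
        Number of tracks and of frames per track.  The default frame
        count (97) covers 24 h at one frame every 15 min.
    dt
        Frame interval in minutes.
    speed_mean, speed_sd
        Per-step speed distribution (truncated normal, floored at 0),
        in µm/min.
    persistence_kappa
        Concentration of heading persistence.  Each step perturbs the
        previous heading by wrapped-normal noise of circular standard
        deviation ``1/sqrt(kappa)`` radians; larger values give
        straighter tracks.
    guidance_weight
        Fraction ``w`` in [0, 1] of steps whose heading is drawn from
        the horizontal guidance axis instead of evolving freely.
    drift_toward_spheroid
        Probability ``p`` that a guided step points toward 0° (the
        spheroid side) rather than 180°.
    arena
        (width, height) in µm over which starting positions are placed
        uniformly.  Tracks may leave the arena; it only fixes the
        initial field of view.
    condition
        Label written to every row of the output table.
    """

    seed: int = 0
    n_cells: int = 1000
    n_frames: int = 97
    dt: float = 15.0
    speed_mean: float = 0.5
    speed_sd: float = 0.15
    persistence_kappa: float = 4.0
    guidance_weight: float = 0.0
    drift_toward_spheroid: float = 0.5
    arena: tuple[float, float] = (2000.0, 2000.0)
    condition: str = "sim"

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_frames <= 1:
            raise ConfigError("n_cells must be >= 1 and n_frames >= 2")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ConfigError("speeds must be non-negative")
        if not 0.0 <= self.guidance_weight <= 1.0:
            raise ConfigError("guidance_weight must lie in [0, 1]")
        if not 0.0 <= self.drift_toward_spheroid <= 1.0:
            raise ConfigError("drift_toward_spheroid must lie in [0, 1]")
        if self.persistence_kappa <= 0:
            raise ConfigError("persistence_kappa must be positive")


def simulate_tracks(cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate migration tracks as a biased persistent random walk.

    Headings evolve by wrapped-normal perturbation of the previous
    heading.  With probability ``guidance_weight`` a step's heading is
    instead re-anchored on the horizontal axis — 0° with probability
    ``drift_toward_spheroid``, 180° otherwise — and perturbed by the
    same wrapped-normal noise, modelling contact guidance along axons.

    Returns
    -------
    DataFrame with columns ``track_id, frame, time_min, x_um, y_um,
    condition``, one row per (track, frame), frames ordered within
    each track.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_cells, cfg.n_frames
    width, height = cfg.arena

    sigma = 1.0 / math.sqrt(cfg.persistence_kappa)

    x = np.empty((n, m))
    y = np.empty((n, m))
    x[:, 0] = rng.uniform(0.0, width, size=n)
    y[:, 0] = rng.uniform(0.0, height, size=n)

    theta = rng.uniform(-np.pi, np.pi, size=n)
    for j in range(1, m):
        noise = rng.normal(0.0, sigma, size=n)
        guided = rng.random(n) < cfg.guidance_weight
        toward = rng.random(n) < cfg.drift_toward_spheroid
        anchor = np.where(toward, 0.0, np.pi)
        theta = np.where(guided, anchor, theta) + noise
        theta = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
        speed = np.maximum(rng.normal(cfg.speed_mean, cfg.speed_sd, size=n), 0.0)
        step = speed * cfg.dt
        x[:, j] = x[:, j - 1] + step * np.cos(theta)
        y[:, j] = y[:, j - 1] + step * np.sin(theta)

    frames = np.tile(np.arange(m), n)
    return pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n), m),
            "frame": frames,
            "time_min": frames * cfg.dt,
            "x_um": x.ravel(),
            "y_um": y.ravel(),
            "condition": cfg.condition,
        }
    )


# ---------------------------------------------------------------------------
# Image synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSynthesisConfig:
    """Parameters of the two-channel endpoint z-stack synthesizer.

    The spheroid (channel 1) is a filled disc whose plane-wise
    intensity follows a smooth axial profile; invading cells
    (channel 2) are isotropic Gaussian spots, each concentrated in one
    z-plane.  Defaults emulate a ~350 µm-diameter spheroid imaged as a
    10-plane stack with 2 µm z-spacing.

    ``snr`` is the peak signal amplitude divided by the additive
    Gaussian noise standard deviation; ``noise_model`` may be
    ``"gaussian"``, ``"poisson"`` or ``"none"``.
    """

    seed: int = 0
    canvas: tuple[int, int, int] = (384, 384, 10)  # rows, cols, planes
    pixel_size: float = 1.5  # µm / px
    z_step: float = 2.0  # µm
    spheroid_center: tuple[float, float] | None = None  # (row, col) px
    spheroid_radius: float = 175.5  # µm
    n_cells_inside: int = 10
    n_cells_outside: int = 20
    cell_sigma: float = 2.0  # px
    cell_amplitude: float = 1.0
    spheroid_amplitude: float = 1.0
    snr: float = 10.0
    noise_model: str = "gaussian"
    min_separation: float = 10.0  # px, 5*cell_sigma keeps spots resolvable
    boundary_margin: float = 5.0  # px, clearance from the disc edge

    def validate(self) -> None:
        rows, cols, planes = self.canvas
        if rows <= 0 or cols <= 0 or planes <= 0:
            raise ConfigError("canvas dimensions must be positive")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ConfigError("pixel_size and z_step must be positive")
        if self.spheroid_radius <= 0:
            raise ConfigError("spheroid_radius must be positive")
        if self.n_cells_inside < 0 or self.n_cells_outside < 0:
            raise ConfigError("cell counts must be non-negative")
        if self.snr <= 0:
            raise ConfigError("snr must be positive")
        if self.noise_model not in {"gaussian", "poisson", "none"}:
            raise ConfigError(f"unknown noise_model: {self.noise_model!r}")
        r_px = self.spheroid_radius / self.pixel_size
        cr, cc = self.center_px()
        if (
            cr - r_px < 0
            or cc - r_px < 0
            or cr + r_px > rows - 1
            or cc + r_px > cols - 1
        ):
            raise ConfigError("spheroid disc extends beyond the canvas")

    def center_px(self) -> tuple[float, float]:
        if self.spheroid_center is not None:
            return self.spheroid_center
        rows, cols, _ = self.canvas
        return ((rows - 1) / 2.0, (cols - 1) / 2.0)


def _place_centroids(
    rng: np.random.Generator, cfg: ImageSynthesisConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample cell centroids inside and outside the disc.

    Centroids keep ``boundary_margin`` px clear of the disc edge (so the
    inside/outside label is unambiguous), ``3*cell_sigma`` px clear of
    the canvas edge, and ``min_separation`` px from each other.
    """
    rows, cols, _ = cfg.canvas
    cr, cc = cfg.center_px()
    r_px = cfg.spheroid_radius / cfg.pixel_size
    edge = 3.0 * cfg.cell_sigma
    placed: list[tuple[float, float]] = []

    def ok(p: tuple[float, float], inside: bool) -> bool:
        d = math.hypot(p[0] - cr, p[1] - cc)
        if inside and d > r_px - cfg.boundary_margin:
            return False
        if not inside and d < r_px + cfg.boundary_margin:
            return False
        for q in placed:
            if math.hypot(p[0] - q[0], p[1] - q[1]) < cfg.min_separation:
                return False
        return True

    def sample(n: int, inside: bool) -> np.ndarray:
        out = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 20000 * max(n, 1):
                raise ConfigError(
                    "could not place cells with the requested separation; "
                    "reduce counts or min_separation"
                )
            if inside:
                ang = rng.uniform(0.0, 2.0 * math.pi)
                rad = (r_px - cfg.boundary_margin) * math.sqrt(rng.uniform())
                p = (cr + rad * math.sin(ang), cc + rad * math.cos(ang))
            else:
                p = (rng.uniform(edge, rows - 1 - edge), rng.uniform(edge, cols - 1 - edge))
            if ok(p, inside):
                placed.append(p)
                out.append(p)
        return np.asarray(out).reshape(n, 2)

    return sample(cfg.n_cells_inside, True), sample(cfg.n_cells_outside, False)


def synthesize_stack(
    cfg: ImageSynthesisConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a two-channel z-stack and its ground-truth table.

    Returns
    -------
    stack : ndarray, shape (2, planes, rows, cols), float32
        Channel 0 is the spheroid nuclear label, channel 1 the
        invading-cell cytoplasmic label.
    truth : DataFrame
        One row per cell: ``cell_id, row_px, col_px, x_um, y_um,
        z_plane, inside`` (centroid in pixel and physical coordinates,
        the plane of peak intensity, and the inside/outside label).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows, cols, planes = cfg.canvas
    cr, cc = cfg.center_px()
    r_px = cfg.spheroid_radius / cfg.pixel_size

    rr, ccg = np.mgrid[0:rows, 0:cols].astype(np.float64)
    disc = ((rr - cr) ** 2 + (ccg - cc) ** 2) <= r_px**2

    # Smooth axial intensity profile peaking mid-stack; keeps every plane
    # informative without modelling real depth attenuation.
    zidx = np.arange(planes)
    zprofile = 0.5 + 0.5 * np.cos((zidx - (planes - 1) / 2.0) / planes * np.pi)

    stack = np.zeros((2, planes, rows, cols), dtype=np.float64)
    stack[0] = cfg.spheroid_amplitude * zprofile[:, None, None] * disc[None, :, :]

    inside, outside = _place_centroids(rng, cfg)
    centroids = np.vstack([inside, outside]) if (len(inside) or len(outside)) else np.empty((0, 2))
    labels = np.array([True] * len(inside) + [False] * len(outside))
    zplanes = rng.integers(0, planes, size=len(centroids))

    two_sigma2 = 2.0 * cfg.cell_sigma**2
    for (pr, pc), zp in zip(centroids, zplanes):
        r0, r1 = int(max(0, pr - 4 * cfg.cell_sigma)), int(min(rows, pr + 4 * cfg.cell_sigma + 1))
        c0, c1 = int(max(0, pc - 4 * cfg.cell_sigma)), int(min(cols, pc + 4 * cfg.cell_sigma + 1))
        sub_r = rr[r0:r1, c0:c1]
        sub_c = ccg[r0:r1, c0:c1]
        spot = cfg.cell_amplitude * np.exp(
            -((sub_r - pr) ** 2 + (sub_c - pc) ** 2) / two_sigma2
        )
        # spot lives mostly in one plane, bleeding into neighbours
        for dz, w in ((-1, 0.4), (0, 1.0), (1, 0.4)):
            z = zp + dz
            if 0 <= z < planes:
                stack[1, z, r0:r1, c0:c1] += w * spot

    if cfg.noise_model == "gaussian":
        noise_sd = np.array([cfg.spheroid_amplitude, cfg.cell_amplitude]) / cfg.snr
        stack += rng.normal(0.0, 1.0, size=stack.shape) * noise_sd[:, None, None, None]
    elif cfg.noise_model == "poisson":
        scale = cfg.snr**2  # photons at peak ~ snr^2 so peak SNR ~ snr
        stack = rng.poisson(np.maximum(stack, 0.0) * scale).astype(np.float64) / scale

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(len(centroids)),
            "row_px": centroids[:, 0] if len(centroids) else np.array([]),
            "col_px": centroids[:, 1] if len(centroids) else np.array([]),
            "z_plane": zplanes,
            "inside": labels,
        }
    )
    truth["x_um"] = truth["col_px"] * cfg.pixel_size
    truth["y_um"] = truth["row_px"] * cfg.pixel_size
    return stack.astype(np.float32), truth


# ---------------------------------------------------------------------------
# Screen count simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSimConfig:
    """Parameters of the plate-level infiltration-count generator.

    Expected raw count for condition *c*, compound *k*, day *d* is::

        baseline + effect_k * cumsum(growth_c)[d]

    where ``growth_c`` lists per-day increments of newly infiltrated
    cells for that condition and ``effect_k`` multiplies infiltration
    (1.0 for vehicle, < 1 for an inhibitor).  Gaussian noise of SD
    ``noise_sd`` is rounded to the nearest integer, added, and the
    result floored at 0 — so at ``noise_sd = 0`` counts equal the
    configured means exactly.  Defaults emulate the study's time
    course: a slow-infiltrating neural-stem-cell control and two
    glioblastoma lines over days 0–5, three replicate experiments,
    with baseline-corrected means rising to ~3 (control), ~10 and ~6.4
    (glioblastoma lines) by day 3.
    """

    seed: int = 0
    conditions: tuple[str, ...] = ("NS", "GB_fast", "GB_slow")
    days: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    n_replicates: int = 3
    baseline: float = 2.0
    growth: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "NS": (0.0, 1.6, 0.7, 0.7, 1.7, 1.8),
            "GB_fast": (0.0, 5.5, 0.0, 4.4, 3.6, 3.7),
            "GB_slow": (0.0, 1.6, 1.5, 3.3, 2.7, 2.8),
        }
    )
    compounds: dict[str, float] = field(default_factory=lambda: {"vehicle": 1.0})
    noise_sd: float = 0.8
    vehicle_label: str = "vehicle"

    def validate(self) -> None:
        if self.n_replicates <= 0:
            raise ConfigError("n_replicates must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for cond in self.conditions:
            if cond not in self.growth:
                raise ConfigError(f"no growth increments for condition {cond!r}")
            if len(self.growth[cond]) != len(self.days):
                raise ConfigError(
                    f"growth for {cond!r} must list one increment per day"
                )
        if self.vehicle_label not in self.compounds:
            raise ConfigError("compounds must include the vehicle")
        if self.compounds[self.vehicle_label] != 1.0:
            raise ConfigError("vehicle compound effect must be 1.0")

    def expected_raw(self, condition: str, compound: str, day: int) -> float:
        """Noise-free expected raw count for one cell of the design."""
        d = list(self.days).index(day)
        cum = float(np.cumsum(self.growth[condition])[d])
        return self.baseline + self.compounds[compound] * cum


def simulate_screen_counts(cfg: ScreenSimConfig) -> pd.DataFrame:
    """Generate a tidy plate count table.

    Returns a DataFrame with columns ``well, condition, compound, day,
    raw_count``; ``well`` identifies a replicate followed across days,
    so per-well baseline correction is meaningful downstream.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for cond in cfg.conditions:
        for comp in cfg.compounds:
            for rep in range(cfg.n_replicates):
                well = f"{cond}|{comp}|r{rep}"
                for day in cfg.days:
                    mean = cfg.expected_raw(cond, comp, day)
                    noise = round(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd else 0.0
                    count = max(mean + noise, 0.0)
                    rows.append(
                        {
                            "well": well,
                            "condition": cond,
                            "compound": comp,
                            "day": day,
                            "raw_count": count,
                        }
                    )
    return pd.DataFrame(rows)
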