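"""Condition-level directional statistics for migration tracks.

Contact guidance along axons shows up as anisotropy in the
distribution of net migration angles.  This module provides the three
summaries used to quantify it:

* polar histograms of net angles (percentage of cells per angular
  bin, one bin centred on 0° — the spheroid direction);
* the Horizontal Preference Index (HPI), a scalar in [−1, 1] that is
  0 in expectation under isotropic migration, +1 when all net motion
  is horizontal and −1 when all net motion is vertical;
* circular uniformity tests (Rayleigh, chi-squared) that ask whether
  the angle distribution could be uniform.

The HPI is defined as magnitude-weighted net-displacement anisotropy

    HPI = Σ_i (|Δx_i| − |Δy_i|) / Σ_i (|Δx_i| + |Δy_i|)

over per-track net displacements (Δx_i, Δy_i).  It is scale-invariant,
negated by a 90° rotation or a reflection across y = x, and ignores
stationary tracks.  A per-step variant pools individual step
displacements instead of net displacements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tracks import MotilitySummary, Track

__all__ = [
    "PolarHistogram",
    "HPIResult",
    "UniformityTests",
    "InsufficientDataError",
    "polar_histogram",
    "compute_hpi",
    "rayleigh_test",
    "chisq_uniformity",
    "uniformity_tests",
]


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


@dataclass(frozen=True)
class PolarHistogram:
    """Angle-binned percentages with one bin centred on 0°."""

    n_bins: int
    bin_width: float  # degrees
    bin_centers: np.ndarray  # degrees, ascending, includes 0
    percentages: np.ndarray  # sums to 100
    n_angles: int


@dataclass(frozen=True)
class HPIResult:
    hpi: float
    n_tracks: int
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class UniformityTests:
    rayleigh_rbar: float
    rayleigh_z: float
    rayleigh_p: float
    chisq_stat: float
    chisq_df: int
    chisq_p: float
    n: int


def polar_histogram(angles_deg, n_bins: int = 36) -> PolarHistogram:
    """Bin net migration angles into ``n_bins`` equal arcs.

    Bins have width 360/n_bins with edges at ±(180/n_bins) around 0°,
    so one bin is centred exactly on the spheroid direction.  Angles
    must lie in (−180, 180]; percentages are 100 × count / total.
    """
    angles = np.asarray(angles_deg, dtype=float)
    angles = angles[~np.isnan(angles)]
    if angles.size == 0:
        raise InsufficientDataError("no angles to bin")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.any(angles <= -180.0) or np.any(angles > 180.0):
        raise ValueError("angles must lie in (-180, 180] degrees")

    width = 360.0 / n_bins
    # shift by half a bin so a bin is centred on 0, then wrap into [0, 360)
    shifted = np.mod(angles + width / 2.0, 360.0)
    idx = np.minimum((shifted // width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    centers = np.mod(np.arange(n_bins) * width + 180.0, 360.0) - 180.0
    order = np.argsort(centers)
    return PolarHistogram(
        n_bins=n_bins,
        bin_width=width,
        bin_centers=centers[order],
        percentages=100.0 * counts[order] / angles.size,
        n_angles=int(angles.size),
    )


def _net_displacements(tracks) -> np.ndarray:
    """(n, 2) array of per-track net displacements from tracks or
    motility summaries; also accepts an (n, 2) array directly."""
    if isinstance(tracks, np.ndarray):
        return np.atleast_2d(np.asarray(tracks, dtype=float))
    out = []
    for t in tracks:
        if isinstance(t, MotilitySummary):
            out.append((t.net_dx, t.net_dy))
        elif isinstance(t, Track):
            out.append((t.x[-1] - t.x[0], t.y[-1] - t.y[0]))
        else:
            dx, dy = t
            out.append((float(dx), float(dy)))
    return np.asarray(out, dtype=float).reshape(-1, 2)


def compute_hpi(
    tracks,
    *,
    per_step: bool = False,
    n_boot: int = 0,
    seed: int | None = None,
) -> HPIResult:
    """Horizontal Preference Index of a set of tracks.

    Parameters
    ----------
    tracks
        Tracks, motility summaries, (Δx, Δy) pairs, or an (n, 2) array
        of net displacements.
    per_step
        Pool per-step displacements of each track instead of net
        displacements (requires Track inputs).
    n_boot
        If > 0, bootstrap a percentile confidence interval by
        resampling tracks with replacement (seeded).
    """
    if per_step:
        disp = np.concatenate(
            [
                np.column_stack((np.diff(t.x), np.diff(t.y)))
                for t in tracks
            ]
        )
    else:
        disp = _net_displacements(tracks)
    mags = np.abs(disp)
    keep = mags.sum(axis=1) > 0
    disp = mags[keep]
    if disp.shape[0] == 0:
        raise InsufficientDataError("all tracks are stationary; HPI undefined")

    def hpi_of(d: np.ndarray) -> float:
        num = float((d[:, 0] - d[:, 1]).sum())
        den = float((d[:, 0] + d[:, 1]).sum())
        return num / den

    value = hpi_of(disp)
    lo = hi = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = disp.shape[0]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            reps[b] = hpi_of(disp[rng.integers(0, n, size=n)])
        lo, hi = (float(q) for q in np.percentile(reps, [2.5, 97.5]))
    return HPIResult(hpi=value, n_tracks=int(disp.shape[0]), ci_low=lo, ci_high=hi)


def rayleigh_test(angles_deg) -> tuple[float, float, float]:
    """Rayleigh test of circular uniformity.

    Returns (R̄, Z, p) with R̄ the mean resultant length, Z = n·R̄²,
    and p from the first-order corrected approximation
    p ≈ exp(−Z)·[1 + (2Z − Z²)/(4n)], clamped to [0, 1].
    """
    angles = np.asarray(angles_deg, dtype=float)
    angles = angles[~np.isnan(angles)]
    n = angles.size
    if n < 5:
        raise InsufficientDataError(f"Rayleigh test needs n >= 5, got {n}")
    rad = np.deg2rad(angles)
    rbar = float(np.hypot(np.cos(rad).sum(), np.sin(rad).sum()) / n)
    z = n * rbar**2
    p = math.exp(-z) * (1.0 + (2.0 * z - z**2) / (4.0 * n))
    return rbar, z, abs(min(max(p, 0.0), 1.0))  # abs() folds -0.0 to 0.0


def chisq_uniformity(angles_deg, n_bins: int = 36) -> tuple[float, int, float]:
    """Chi-squared goodness-of-fit test against the uniform circle.

    Observed counts come from :func:`polar_histogram` bins; expected
    count per bin is n/n_bins.  Warns when the expected count drops
    below 5 (the usual validity rule of thumb).
    """
    hist = polar_histogram(angles_deg, n_bins=n_bins)
    n = hist.n_angles
    expected = n / n_bins
    if expected < 5:
        warnings.warn(
            f"expected count per bin is {expected:.2f} < 5; "
            "chi-squared approximation may be poor",
            stacklevel=2,
        )
    observed = hist.percentages * n / 100.0
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = n_bins - 1
    return stat, df, float(stats.chi2.sf(stat, df))


def uniformity_tests(angles_deg, n_bins: int = 36) -> UniformityTests:
    """Run both uniformity tests on one set of angles."""
    angles = np.asarray(angles_deg, dtype=float)
    angles = angles[~np.isnan(angles)]
    rbar, z, p_ray = rayleigh_test(angles)
    stat, df, p_chi = chisq_uniformity(angles, n_bins=n_bins)
    return UniformityTests(
        rayleigh_rbar=rbar,
        rayleigh_z=z,
        rayleigh_p=p_ray,
        chisq_stat=stat,
        chisq_df=df,
        chisq_p=p_chi,
        n=int(angles.size),
    )
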