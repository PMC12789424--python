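"""File I/O for image stacks and their calibration sidecars.

Stacks are stored as multi-page TIFF with pages ordered channel-major
(channel 0 planes first, then channel 1), and a YAML sidecar holding
the physical calibration (pixel size, z-step) and the channel/plane
layout, since plain multi-page TIFF carries no such metadata.
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["write_stack", "read_stack"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(
    path: str | PathLike,
    stack: np.ndarray,
    *,
    pixel_size: float,
    z_step: float,
    channel_names: tuple[str, str] = ("spheroid", "cells"),
) -> None:
    """Write a (channels, planes, rows, cols) stack + YAML sidecar."""
    path = Path(path)
    arr = np.asarray(stack)
    if arr.ndim != 4:
        raise ValueError("stack must be (channels, planes, rows, cols)")
    pages = arr.reshape(-1, arr.shape[2], arr.shape[3])
    tifffile.imwrite(path, pages)
    meta = {
        "pixel_size_um": float(pixel_size),
        "z_step_um": float(z_step),
        "n_channels": int(arr.shape[0]),
        "n_planes": int(arr.shape[1]),
        "channel_names": list(channel_names),
        "page_order": "channel-major",
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_stack(path: str | PathLike) -> tuple[np.ndarray, dict]:
    """Read a stack written by :func:`write_stack`.

    Returns the (channels, planes, rows, cols) array and the sidecar
    metadata dict.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing calibration sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    nc, nz = int(meta["n_channels"]), int(meta["n_planes"])
    if pages.shape[0] != nc * nz:
        raise ValueError(
            f"TIFF has {pages.shape[0]} pages but sidecar declares "
            f"{nc} channels x {nz} planes"
        )
    return pages.reshape(nc, nz, pages.shape[1], pages.shape[2]), meta
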