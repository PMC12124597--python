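"""Synthetic absorber phantoms: disks/spheres and random vessel trees.

These stand in for the vascular structures used in experimental work so
that the whole pipeline can be exercised without any external data. Values
are unitless initial pressure; absolute scale does not matter downstream
because images are min-max normalized before optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import ImageGrid

__all__ = ["PhantomError", "Phantom", "make_disk_phantom", "make_vessel_phantom"]


class PhantomError(ValueError):
    """Raised for invalid phantom specifications."""


@dataclass(frozen=True)
class Phantom:
    """Non-negative initial-pressure field on a regular grid."""

    grid: ImageGrid
    values: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise PhantomError(
                f"values shape {vals.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise PhantomError("phantom values must be finite")
        if np.any(vals < 0):
            raise PhantomError("phantom values must be non-negative")
        if not np.any(vals > 0):
            raise PhantomError("phantom must contain at least one positive voxel")
        object.__setattr__(self, "values", vals)


def make_disk_phantom(
    grid: ImageGrid,
    disks: list[tuple[tuple[float, ...], float, float]],
) -> Phantom:
    """Sum of uniform disks (2D) or spheres (3D).

    Each entry of ``disks`` is ``(center, radius, amplitude)`` in meters /
    arbitrary units. A voxel receives the amplitude of every disk whose
    center-to-voxel-center distance is at most the disk radius.
    """
    if not disks:
        raise PhantomError("disk list must not be empty")
    centers = grid.voxel_centers()
    values = np.zeros(grid.n_voxels)
    for center, radius, amplitude in disks:
        center = np.asarray(center, dtype=float)
        if center.shape != (grid.dim,):
            raise PhantomError("disk center dimensionality must match the grid")
        if radius <= 0:
            raise PhantomError("disk radius must be positive")
        if amplitude <= 0:
            raise PhantomError("disk amplitude must be positive")
        dist = np.linalg.norm(centers - center, axis=1)
        values[dist <= radius] += amplitude
    return Phantom(grid, values.reshape(grid.shape), description=f"{len(disks)} disk(s)")


def make_vessel_phantom(grid: ImageGrid, seed: int, n_branches: int = 6) -> Phantom:
    """Random-walk tubular branches with smooth Gaussian cross-sections.

    Branches start at random interior points, walk with slowly drifting
    directions, and are rasterized onto the grid; a Gaussian blur gives the
    tubes a smooth profile. Output values lie in [0, 1] and the phantom is a
    pure function of ``(grid, seed, n_branches)``.
    """
    if n_branches < 1:
        raise PhantomError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    shape = np.asarray(grid.shape)
    canvas = np.zeros(grid.shape)
    n_steps = int(2.5 * shape.max())
    for _ in range(n_branches):
        # start away from the border so branches mostly stay inside
        pos = shape * (0.25 + 0.5 * rng.random(grid.dim))
        direction = rng.normal(size=grid.dim)
        direction /= np.linalg.norm(direction)
        weight = 0.5 + 0.5 * rng.random()
        for _ in range(n_steps):
            direction += 0.35 * rng.normal(size=grid.dim)
            direction /= np.linalg.norm(direction)
            pos = pos + direction
            idx = np.round(pos).astype(int)
            if np.any(idx < 0) or np.any(idx >= shape):
                break
            canvas[tuple(idx)] = max(canvas[tuple(idx)], weight)
    if not np.any(canvas > 0):
        # pathological seed: every walk left immediately; drop one marker
        canvas[tuple(shape // 2)] = 1.0
    sigma = max(1.0, 0.006 * float(shape.max()))
    smooth = gaussian_filter(canvas, sigma=sigma)
    smooth /= smooth.max()
    # soft threshold keeps tubes compact while preserving the smooth profile
    smooth[smooth < 0.05] = 0.0
    return Phantom(grid, smooth, description=f"vessel seed={seed} branches={n_branches}")
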