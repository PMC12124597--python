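"""Detector array geometries and regular imaging grids.

Conventions used throughout the package:

* all coordinates are in SI meters;
* grid indices are 0-based and row-major;
* the scalar value of a voxel lives at the voxel *center*, and voxel
  centers are ``origin + index * spacing`` (elementwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "ArrayGeometry",
    "ImageGrid",
    "make_ring_array",
    "make_hemisphere_array",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class GeometryError(ValueError):
    """Raised for geometrically invalid array or grid definitions."""


@dataclass(frozen=True)
class ArrayGeometry:
    """A set of point-like detector elements.

    Parameters
    ----------
    positions
        ``(n_elements, dim)`` float array of element coordinates in meters,
        with ``dim`` either 2 or 3.
    label
        Free-text description of the array (kept in file metadata).
    radius
        Optional nominal radius in meters for ring/hemisphere arrays.
    """

    positions: np.ndarray
    label: str = ""
    radius: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] not in (2, 3):
            raise GeometryError(
                f"positions must be (N, 2) or (N, 3), got shape {pos.shape}"
            )
        if pos.shape[0] < 1:
            raise GeometryError("geometry needs at least one element")
        if not np.all(np.isfinite(pos)):
            raise GeometryError("element positions must be finite")
        # duplicate elements would silently double-weight a view
        uniq = np.unique(pos, axis=0)
        if uniq.shape[0] != pos.shape[0]:
            raise GeometryError("element positions must be distinct")
        object.__setattr__(self, "positions", pos)

    @property
    def n_elements(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class ImageGrid:
    """Regular 2D/3D grid; ``origin`` is the center of voxel (0, ..., 0)."""

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) not in (2, 3):
            raise GeometryError("grid must be 2D or 3D")
        if len(spacing) != len(shape):
            raise GeometryError("spacing must have one entry per axis")
        if any(s < 1 for s in shape):
            raise GeometryError("all shape entries must be >= 1")
        if any(d <= 0 for d in spacing):
            raise GeometryError("all spacings must be > 0")
        origin = self.origin
        if origin is None:
            # default: grid centered on the coordinate origin
            origin = tuple(-(n - 1) * d / 2.0 for n, d in zip(shape, spacing))
        origin = tuple(float(o) for o in origin)
        if len(origin) != len(shape):
            raise GeometryError("origin must have one entry per axis")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def dim(self) -> int:
        return len(self.shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, ...]:
        """Per-axis voxel-center coordinates."""
        return tuple(
            o + np.arange(n) * d
            for n, d, o in zip(self.shape, self.spacing, self.origin)
        )

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center coordinates, shape ``(n_voxels, dim)``, row-major."""
        mesh = np.meshgrid(*self.axes(), indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)


def make_ring_array(
    n_elements: int, radius: float, center: tuple[float, float] = (0.0, 0.0)
) -> ArrayGeometry:
    """Full circular ring of equally spaced elements.

    Element ``i`` sits at angle ``2*pi*i/n_elements`` counterclockwise from
    the +x axis.
    """
    if n_elements < 3:
        raise GeometryError("a ring array needs at least 3 elements")
    if radius <= 0:
        raise GeometryError("ring radius must be positive")
    theta = 2.0 * np.pi * np.arange(n_elements) / n_elements
    pos = np.stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)],
        axis=-1,
    )
    return ArrayGeometry(pos, label=f"ring N={n_elements} r={radius}", radius=radius)


def make_hemisphere_array(
    n_elements: int, radius: float, pole_hole_height: float = 0.0
) -> ArrayGeometry:
    """Detection bowl: quasi-uniform elements on the hemisphere ``z <= 0``.

    Elements are laid out with a Fibonacci (golden-angle) scheme restricted
    to the spherical band between the equator and the illumination aperture,
    a spherical cap of height ``pole_hole_height`` around the pole that is
    kept element-free. The layout is deterministic.
    """
    if n_elements < 1:
        raise GeometryError("need at least one element")
    if radius <= 0:
        raise GeometryError("radius must be positive")
    if not 0 <= pole_hole_height < radius:
        raise GeometryError("pole hole height must satisfy 0 <= h < radius")
    # band of allowed z: cap of height h around z=-r is excluded
    z_lo = -(radius - pole_hole_height)
    z_hi = 0.0
    i = np.arange(n_elements)
    z = z_lo + (i + 0.5) * (z_hi - z_lo) / n_elements
    rho = np.sqrt(np.maximum(radius**2 - z**2, 0.0))
    phi = i * _GOLDEN_ANGLE
    pos = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=-1)
    return ArrayGeometry(
        pos,
        label=f"hemisphere N={n_elements} r={radius} hole={pole_hole_height}",
        radius=radius,
    )
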