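"""Delay-and-sum and universal back-projection reconstruction.

Both algorithms back-project each element's trace at the geometric time of
flight to every voxel, with linear temporal interpolation and uniform
(element-exchangeable) weights normalized by the number of elements used.
That normalization makes subset reconstructions and the full-array
reconstruction share one scale, and gives the subset-mean identity: the
full-array image equals the mean of the images from any disjoint partition
of the elements. UBP differs from DAS only in applying the filter
``b(t) = 2 p(t) - 2 t dp/dt`` to the traces first. No solid-angle
weighting is applied.

Negative values are retained; absolute value is taken only at
presentation/metric time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .forward import ChannelData
from .geometry import ImageGrid

__all__ = ["ReconImage", "das_reconstruct", "ubp_filter", "ubp_reconstruct"]


@dataclass(frozen=True)
class ReconImage:
    """Reconstructed scalar field on a regular grid, with provenance text."""

    grid: ImageGrid
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise ValueError(
                f"values shape {vals.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("reconstructed values must be finite")
        object.__setattr__(self, "values", vals)


def _check_elements(elements: Sequence[int] | None, n: int) -> np.ndarray:
    if elements is None:
        return np.arange(n)
    idx = np.asarray(list(elements), dtype=int)
    if idx.size == 0:
        raise ValueError("element subset must not be empty")
    if np.any(idx < 0) or np.any(idx >= n):
        raise IndexError(f"element indices must lie in [0, {n})")
    return idx


def _backproject(
    data: ChannelData, grid: ImageGrid, elements: np.ndarray
) -> np.ndarray:
    if grid.dim != data.geometry.dim:
        raise ValueError("grid and geometry dimensionality differ")
    params = data.params
    centers = grid.voxel_centers()
    image = np.zeros(grid.n_voxels)
    m = params.n_samples
    for d in elements:
        dist = np.linalg.norm(centers - data.geometry.positions[d], axis=1)
        tau = (dist / params.sound_speed - params.t0) * params.sampling_rate
        lo = np.floor(tau).astype(int)
        frac = tau - lo
        # out-of-window delays contribute zero (no clamping)
        valid = (lo >= 0) & (lo < m - 1)
        trace = data.traces[d]
        contrib = np.zeros_like(image)
        contrib[valid] = (
            (1.0 - frac[valid]) * trace[lo[valid]] + frac[valid] * trace[lo[valid] + 1]
        )
        image += contrib
    image /= elements.size
    return image.reshape(grid.shape)


def das_reconstruct(
    data: ChannelData, grid: ImageGrid, elements: Sequence[int] | None = None
) -> ReconImage:
    """Delay-and-sum beamforming over the given element subset (default: all)."""
    idx = _check_elements(elements, data.n_elements)
    img = _backproject(data, grid, idx)
    return ReconImage(grid, img, provenance=f"das elements={idx.size}/{data.n_elements}")


def ubp_filter(data: ChannelData) -> ChannelData:
    """Apply the universal back-projection filter ``2 p(t) - 2 t dp/dt``.

    ``t`` is the absolute sample time ``t0 + m/fs``; the derivative uses
    central differences in the interior and one-sided differences at the
    trace ends.
    """
    if data.n_samples < 3:
        raise ValueError("UBP filtering requires at least 3 samples")
    t = data.params.sample_times()
    dp = np.gradient(data.traces, data.params.dt, axis=1)
    filtered = 2.0 * data.traces - 2.0 * t[None, :] * dp
    return ChannelData(filtered, data.geometry, data.params)


def ubp_reconstruct(
    data: ChannelData, grid: ImageGrid, elements: Sequence[int] | None = None
) -> ReconImage:
    """Universal back-projection: DAS applied to the UBP-filtered traces."""
    idx = _check_elements(elements, data.n_elements)
    img = _backproject(ubp_filter(data), grid, idx)
    return ReconImage(grid, img, provenance=f"ubp elements={idx.size}/{data.n_elements}")
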