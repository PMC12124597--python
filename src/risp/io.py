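"""Readers and writers for the interchange formats.

Channel data travels as HDF5 with the layout::

    /channel_data          (N, M) float32    pressure traces
        @sampling_rate_hz, @sound_speed_mps, @t0_s
    /geometry/positions    (N, dim) float64  element coordinates, meters
        @radius (optional), @label (optional)

Images travel as float32 TIFF (2D, spacing in the resolution tags) or
NIfTI-1 (3D, spacing in pixdim, millimeters per NIfTI convention). Subset
plans and metric reports are JSON; configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile
import yaml

from .forward import AcquisitionParams, ChannelData
from .geometry import ArrayGeometry, ImageGrid
from .prior import SubsetPlan
from .recon import ReconImage

__all__ = [
    "write_channel_data",
    "read_channel_data",
    "write_image",
    "read_image",
    "write_subset_plan",
    "read_subset_plan",
    "write_json",
    "read_yaml",
]


def write_channel_data(path: str | Path, data: ChannelData) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("channel_data", data=data.traces.astype(np.float32))
        ds.attrs["sampling_rate_hz"] = data.params.sampling_rate
        ds.attrs["sound_speed_mps"] = data.params.sound_speed
        ds.attrs["t0_s"] = data.params.t0
        g = f.create_group("geometry")
        pos = g.create_dataset("positions", data=data.geometry.positions.astype(np.float64))
        if data.geometry.radius is not None:
            pos.attrs["radius"] = data.geometry.radius
        pos.attrs["label"] = data.geometry.label


def read_channel_data(path: str | Path) -> ChannelData:
    with h5py.File(path, "r") as f:
        ds = f["channel_data"]
        traces = np.asarray(ds, dtype=float)
        params = AcquisitionParams(
            sound_speed=float(ds.attrs["sound_speed_mps"]),
            sampling_rate=float(ds.attrs["sampling_rate_hz"]),
            n_samples=traces.shape[1],
            t0=float(ds.attrs.get("t0_s", 0.0)),
        )
        pos = f["geometry/positions"]
        geometry = ArrayGeometry(
            np.asarray(pos, dtype=float),
            label=str(pos.attrs.get("label", "")),
            radius=float(pos.attrs["radius"]) if "radius" in pos.attrs else None,
        )
    return ChannelData(traces, geometry, params)


def write_image(path: str | Path, image: ReconImage) -> None:
    """Write 2D images as float32 TIFF, 3D volumes as NIfTI-1."""
    path = Path(path)
    vals = image.values.astype(np.float32)
    if image.grid.dim == 2:
        dy, dx = image.grid.spacing
        # TIFF resolution tags are pixels per unit; store pixels/cm
        tifffile.imwrite(
            path,
            vals,
            resolution=(1e-2 / dx, 1e-2 / dy),
            resolutionunit="CENTIMETER",
            metadata={"spacing_m": list(image.grid.spacing),
                      "origin_m": list(image.grid.origin)},
        )
    else:
        affine = np.diag([*(s * 1e3 for s in image.grid.spacing), 1.0])
        affine[:3, 3] = [o * 1e3 for o in image.grid.origin]
        nib.save(nib.Nifti1Image(vals, affine), str(path))


def read_image(path: str | Path, grid: ImageGrid | None = None) -> ReconImage:
    """Read a TIFF/NIfTI image; grid metadata is recovered where stored."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            vals = tf.asarray().astype(float)
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if grid is None:
            spacing = meta.get("spacing_m")
            origin = meta.get("origin_m")
            grid = ImageGrid(
                vals.shape,
                tuple(spacing) if spacing else (1.0,) * vals.ndim,
                tuple(origin) if origin else None,
            )
    else:
        img = nib.load(str(path))
        vals = np.asarray(img.dataobj, dtype=float)
        if grid is None:
            zooms = img.header.get_zooms()[: vals.ndim]
            origin = img.affine[: vals.ndim, 3]
            grid = ImageGrid(
                vals.shape,
                tuple(z * 1e-3 for z in zooms),
                tuple(o * 1e-3 for o in origin),
            )
    return ReconImage(grid, vals, provenance=f"loaded from {path.name}")


def write_subset_plan(path: str | Path, plan: SubsetPlan) -> None:
    Path(path).write_text(json.dumps(plan.to_dict(), indent=2) + "\n")


def read_subset_plan(path: str | Path) -> SubsetPlan:
    d = json.loads(Path(path).read_text())
    return SubsetPlan(
        tuple(tuple(int(i) for i in sub) for sub in d["subsets"]),
        int(d["n_elements"]),
        int(d["seed"]),
    )


def write_json(path: str | Path, obj: dict) -> None:
    """Deterministic JSON dump (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
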