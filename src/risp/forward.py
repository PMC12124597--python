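"""Analytic forward simulation of photoacoustic channel data.

A phantom's initial pressure is projected onto each detector by a
discretized circular-mean (2D) / spherical-mean (3D) transform followed by
a temporal derivative. This is a linear desk-scale surrogate for full-wave
acoustic propagation: it reproduces the geometric times of flight and the
wideband bipolar pulse shape that drive sparse-view streak artifacts,
which is what the downstream coherence prior operates on. It does not
model acoustic heterogeneity, attenuation, or element directivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ArrayGeometry
from .phantom import Phantom

__all__ = [
    "AcquisitionParams",
    "ChannelData",
    "TimeWindowError",
    "simulate_channel_data",
    "add_noise",
]


class TimeWindowError(ValueError):
    """Raised when the acquisition window does not cover the imaging volume."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Sampling metadata shared by simulation and reconstruction.

    sound_speed in m/s, sampling_rate in Hz, t0 the absolute time of the
    first sample in seconds.
    """

    sound_speed: float
    sampling_rate: float
    n_samples: int
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def sample_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class ChannelData:
    """N x M pressure traces with their geometry and sampling metadata."""

    traces: np.ndarray
    geometry: ArrayGeometry
    params: AcquisitionParams

    def __post_init__(self) -> None:
        tr = np.asarray(self.traces, dtype=float)
        if tr.ndim != 2:
            raise ValueError("traces must be a 2D (N, M) array")
        if tr.shape[0] != self.geometry.n_elements:
            raise ValueError(
                f"traces have {tr.shape[0]} rows but geometry has "
                f"{self.geometry.n_elements} elements"
            )
        if tr.shape[1] != self.params.n_samples:
            raise ValueError(
                f"traces have {tr.shape[1]} columns but params.n_samples is "
                f"{self.params.n_samples}"
            )
        if not np.all(np.isfinite(tr)):
            raise ValueError("traces must be finite")
        object.__setattr__(self, "traces", tr)

    @property
    def n_elements(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]


def simulate_channel_data(
    phantom: Phantom, geometry: ArrayGeometry, params: AcquisitionParams
) -> ChannelData:
    """Simulate traces by shell binning plus a central-difference derivative.

    For detector ``d`` and sample ``m`` the mean initial pressure over the
    annulus/shell ``|r_v - r_d| in [c*t_m - delta/2, c*t_m + delta/2)`` with
    ``delta = c/fs`` is accumulated (voxel contributions are nearest-bin,
    normalized by the analytic shell measure), then differentiated in time.
    """
    if phantom.grid.dim != geometry.dim:
        raise ValueError("phantom grid and geometry dimensionality differ")
    c = params.sound_speed
    delta = c * params.dt
    centers = phantom.grid.voxel_centers()
    values = phantom.values.ravel()
    nz = values != 0
    centers, values = centers[nz], values[nz]
    vol = phantom.grid.voxel_volume

    n_det, m = geometry.n_elements, params.n_samples
    g = np.zeros((n_det, m))
    # shell radii at bin centers; bin 0 may sit at r ~ 0 -> floor the measure
    r_bins = np.maximum(c * params.sample_times(), delta / 2.0)
    if geometry.dim == 2:
        shell_measure = 2.0 * np.pi * r_bins * delta
    else:
        shell_measure = 4.0 * np.pi * r_bins**2 * delta

    if centers.size:
        max_dist = 0.0
        for d in range(n_det):
            dist = np.linalg.norm(centers - geometry.positions[d], axis=1)
            max_dist = max(max_dist, float(dist.max()))
            # half-open bins [c*t - delta/2, c*t + delta/2)
            bins = np.floor((dist / c - params.t0) / params.dt + 0.5).astype(int)
            valid = (bins >= 0) & (bins < m)
            if np.any(bins >= m):
                t_end = params.t0 + (m - 1) * params.dt
                raise TimeWindowError(
                    f"time window [t0, t0+(M-1)/fs] = [{params.t0:g}, {t_end:g}] s "
                    f"too short: need M >= "
                    f"{int(np.ceil((max_dist / c - params.t0) / params.dt)) + 2} "
                    f"samples to cover the farthest voxel"
                )
            g[d] = np.bincount(bins[valid], weights=values[valid], minlength=m)
        g *= vol / shell_measure

    traces = np.gradient(g, params.dt, axis=1)
    return ChannelData(traces, geometry, params)


def add_noise(data: ChannelData, snr_db: float | None, seed: int = 0) -> ChannelData:
    """Add white Gaussian noise at the requested SNR (dB). ``None`` = no noise."""
    if snr_db is None:
        return data
    signal_power = float(np.mean(data.traces**2))
    if signal_power == 0:
        raise ValueError("cannot scale noise for all-zero traces")
    noise_power = signal_power / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=np.sqrt(noise_power), size=data.traces.shape)
    return ChannelData(data.traces + noise, data.geometry, data.params)
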