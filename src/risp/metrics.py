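"""Image-quality metrics: PSNR, SSIM, CNR, and line-profile correlation.

All full-image metrics follow the presentation convention used for
reconstructed images: compare magnitudes, each image independently min-max
normalized to [0, 1] (see :func:`prepare_for_metrics`). PSNR then uses
peak 1 and SSIM data range 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = [
    "MetricReport",
    "prepare_for_metrics",
    "psnr",
    "ssim",
    "cnr",
    "line_correlation",
    "evaluate",
]


@dataclass(frozen=True)
class MetricReport:
    psnr_db: float
    ssim: float
    cnr_db: float | None = None
    correlations: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out: dict = {
            "psnr_db": None if np.isinf(self.psnr_db) else self.psnr_db,
            "ssim": self.ssim,
        }
        if self.cnr_db is not None:
            out["cnr_db"] = self.cnr_db
        if self.correlations is not None:
            out["correlations"] = dict(self.correlations)
        return out


def prepare_for_metrics(values: np.ndarray) -> np.ndarray:
    """Absolute value then independent min-max normalization to [0, 1]."""
    mag = np.abs(np.asarray(values, dtype=float))
    lo, hi = float(mag.min()), float(mag.max())
    if hi - lo <= 0:
        return np.zeros_like(mag)
    return (mag - lo) / (hi - lo)


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB with peak value 1.

    Inputs are expected on the [0, 1] scale. Identical images return
    ``inf`` (the MSE = 0 sentinel).
    """
    if reference.shape != test.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((np.asarray(reference, float) - np.asarray(test, float)) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(1.0 / mse)


def ssim(reference: np.ndarray, test: np.ndarray) -> float:
    """Mean structural similarity with the standard constants.

    Uses K1=0.01, K2=0.03 on data range 1 with a 7-wide window (2D and 3D
    alike); Gaussian weighting is off, matching the classic uniform-window
    definition.
    """
    if reference.shape != test.shape:
        raise ValueError("shape mismatch")
    if min(reference.shape) < 7:
        raise ValueError("image smaller than the 7-wide SSIM window")
    return float(
        structural_similarity(
            np.asarray(reference, float),
            np.asarray(test, float),
            data_range=1.0,
            win_size=7,
            K1=0.01,
            K2=0.03,
        )
    )


def _box_slices(box: tuple[tuple[int, int], ...]) -> tuple[slice, ...]:
    return tuple(slice(lo, hi) for lo, hi in box)


def cnr(
    image: np.ndarray,
    signal_region: tuple[tuple[int, int], ...],
    noise_region: tuple[tuple[int, int], ...],
    amplitude: bool = True,
) -> float:
    """Contrast-to-noise ratio between two index boxes, in dB.

    Boxes are per-axis half-open index ranges ``((lo, hi), ...)`` and must
    be disjoint and non-empty. The default is the amplitude-ratio
    convention ``20*log10(|mean_s - mean_n| / std_n)``; ``amplitude=False``
    selects the power-ratio convention with factor 10.
    """
    if len(signal_region) != image.ndim or len(noise_region) != image.ndim:
        raise ValueError("boxes must give one (lo, hi) range per image axis")
    for box in (signal_region, noise_region):
        for ax, (lo, hi) in enumerate(box):
            if not 0 <= lo < hi <= image.shape[ax]:
                raise ValueError("box out of bounds or empty")
    # disjoint iff they are separated along at least one axis
    overlapping = all(
        s_lo < n_hi and n_lo < s_hi
        for (s_lo, s_hi), (n_lo, n_hi) in zip(signal_region, noise_region)
    )
    if overlapping:
        raise ValueError("signal and noise regions must be disjoint")
    sig = image[_box_slices(signal_region)]
    noi = image[_box_slices(noise_region)]
    noise_std = float(np.std(noi))
    if noise_std == 0:
        raise ValueError("noise region has zero standard deviation")
    ratio = abs(float(np.mean(sig)) - float(np.mean(noi))) / noise_std
    factor = 20.0 if amplitude else 10.0
    if ratio == 0:
        return float("-inf")
    return factor * np.log10(ratio)


def line_correlation(
    reference: np.ndarray, test: np.ndarray, line: list[tuple[int, ...]]
) -> float:
    """Pearson correlation of intensity profiles along a voxel path."""
    if len(line) < 3:
        raise ValueError("line must contain at least 3 voxels")
    idx = tuple(np.asarray([p[ax] for p in line]) for ax in range(reference.ndim))
    prof_ref = np.asarray(reference, float)[idx]
    prof_test = np.asarray(test, float)[idx]
    if np.std(prof_ref) == 0 or np.std(prof_test) == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    return float(stats.pearsonr(prof_ref, prof_test).statistic)


def evaluate(
    reference: np.ndarray,
    test: np.ndarray,
    cnr_boxes: tuple | None = None,
    lines: dict[str, list[tuple[int, ...]]] | None = None,
) -> MetricReport:
    """PSNR/SSIM (plus optional CNR and line correlations) on prepared images."""
    ref = prepare_for_metrics(reference)
    tst = prepare_for_metrics(test)
    cnr_db = None
    if cnr_boxes is not None:
        cnr_db = cnr(tst, *cnr_boxes)
    correlations = None
    if lines:
        correlations = {name: line_correlation(ref, tst, line) for name, line in lines.items()}
    return MetricReport(psnr(ref, tst), ssim(ref, tst), cnr_db, correlations)
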