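"""Stationary ("a trous") B3-spline wavelet decomposition for spot detection.

The undecimated a trous transform convolves the image with a separable
B3-spline kernel (1, 4, 6, 4, 1)/16 whose taps are spread apart by inserting
2**(j-1) - 1 zeros ("holes") at level j.  Each detail plane

    w_j = c_{j-1} - c_j,        c_0 = image

isolates structures of characteristic size ~2**j pixels, which makes single
planes excellent matched filters for round diffraction-limited spots.  The
transform is exactly invertible by summation: sum_j w_j + c_J = image.

Noise is removed per plane by hard thresholding at k * sigma_j, with sigma_j
estimated robustly from the plane itself (MAD / 0.6745 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

# B3-spline scaling kernel, the canonical choice for a trous spot detection.
B3_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

#: Gaussian consistency constant: sigma = MAD / 0.6745.
MAD_TO_SD = 0.6745


@dataclass
class ThresholdPolicy:
    """Hard-threshold rule applied per detail plane.

    Parameters
    ----------
    k : float
        Threshold multiplier; coefficients with ``|w| < k * sigma_j`` are
        zeroed.  ``k = 0`` leaves planes unchanged.
    estimator : {"mad", "sd"}
        Per-plane noise-scale estimator.  ``"mad"`` uses the median absolute
        deviation scaled to Gaussian sigma; ``"sd"`` uses the plane standard
        deviation.
    """

    k: float = 3.0
    estimator: str = "mad"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"threshold multiplier k must be >= 0, got {self.k}")
        if self.estimator not in ("mad", "sd"):
            raise ValueError(f"unknown noise estimator {self.estimator!r}")

    def sigma(self, plane: np.ndarray) -> float:
        if self.estimator == "mad":
            return float(np.median(np.abs(plane - np.median(plane)))) / MAD_TO_SD
        return float(plane.std())


@dataclass
class WaveletPlanes:
    """Detail planes ``w_1..w_J`` plus the smooth residual ``c_J``."""

    detail: list[np.ndarray]
    residual: np.ndarray
    kernel_id: str = "b3-spline"

    @property
    def levels(self) -> int:
        return len(self.detail)

    def reconstruct(self) -> np.ndarray:
        """Invert the transform: element-wise sum of all planes."""
        return sum(self.detail) + self.residual


def _kernel_at_level(level: int) -> np.ndarray:
    """B3 kernel with 2**(level-1) - 1 zeros inserted between taps."""
    holes = 2 ** (level - 1) - 1
    kernel = np.zeros(len(B3_KERNEL) + holes * (len(B3_KERNEL) - 1))
    kernel[:: holes + 1] = B3_KERNEL
    return kernel


def max_levels(shape: tuple[int, ...]) -> int:
    """Largest J such that the level-J kernel support fits min(shape)."""
    j = 0
    while min(shape) > 2 ** (j + 1) * 4:
        j += 1
    return j


def decompose(image: np.ndarray, levels: int = 4) -> WaveletPlanes:
    """A trous decomposition of a 2D image into ``levels`` detail planes.

    Uses symmetric (reflect) boundary handling; the transform is stationary,
    so every plane has the input shape and the decomposition commutes with
    translation away from the borders.

    Raises
    ------
    ValueError
        If the image is too small for the requested number of levels; the
        message names the maximum feasible J.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={image.ndim}")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    feasible = max_levels(image.shape)
    if levels > feasible:
        raise ValueError(
            f"image of shape {image.shape} supports at most J={feasible} "
            f"levels; requested {levels}"
        )

    detail: list[np.ndarray] = []
    c_prev = image
    for j in range(1, levels + 1):
        kernel = _kernel_at_level(j)
        c = convolve1d(c_prev, kernel, axis=0, mode="reflect")
        c = convolve1d(c, kernel, axis=1, mode="reflect")
        detail.append(c_prev - c)
        c_prev = c
    return WaveletPlanes(detail=detail, residual=c_prev)


def threshold_planes(
    planes: WaveletPlanes, policy: ThresholdPolicy | None = None
) -> WaveletPlanes:
    """Hard-threshold each detail plane at ``k * sigma_j``; residual untouched."""
    if policy is None:
        policy = ThresholdPolicy()
    out = []
    for w in planes.detail:
        t = policy.k * policy.sigma(w)
        out.append(np.where(np.abs(w) < t, 0.0, w))
    return WaveletPlanes(detail=out, residual=planes.residual.copy(),
                         kernel_id=planes.kernel_id)


def select_scale(spot_diameter: float, pixel_size: float, levels: int) -> int:
    """Scale index whose size bracket matches a spot diameter (in um).

    ``j* = round(log2(d_px))`` clamped below at 1; a spot larger than the
    decomposition can represent raises with a suggestion for J.
    """
    if spot_diameter <= 0:
        raise ValueError("spot_diameter must be > 0")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    d_px = spot_diameter / pixel_size
    j = int(round(np.log2(d_px))) if d_px > 1 else 1
    if j > levels:
        raise ValueError(
            f"spot diameter {d_px:.1f} px needs scale {j}; decomposition has "
            f"only J={levels} levels — decompose with levels >= {j}"
        )
    return max(j, 1)


def spot_response(
    planes: WaveletPlanes,
    spot_diameter: float,
    pixel_size: float,
    multiscale: bool = False,
) -> np.ndarray:
    """Positive part of the detail plane matched to the spot size.

    With ``multiscale=True`` the planes j*-1, j*, j*+1 (those that exist) are
    summed before clipping, trading scale selectivity for robustness.  Spots
    are bright, so negative coefficients carry no spot signal and are clipped
    here (and only here).
    """
    j_star = select_scale(spot_diameter, pixel_size, planes.levels)
    if multiscale:
        lo, hi = max(1, j_star - 1), min(planes.levels, j_star + 1)
        resp = sum(planes.detail[j - 1] for j in range(lo, hi + 1))
    else:
        resp = planes.detail[j_star - 1]
    return np.clip(resp, 0.0, None)
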