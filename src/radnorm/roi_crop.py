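"""Percentile-bounded ROI cropping driven by axis-wise intensity-mass CDFs.

The crop works in three steps: (1) project the image onto each axis as a
grayscale-sum profile, (2) normalize the cumulative profile into a mass CDF,
(3) retain the index window whose CDF values lie in the half-open mass
interval ``lo < cdf[i] <= hi``.  On a uniform image this retains exactly the
central ``hi - lo`` fraction of columns/rows.  Defaults keep the 5th-95th
mass percentiles horizontally and the 15th-95th vertically, which discards
low-density lateral background and the bright band above the clavicles.

Both axis windows are computed from the ORIGINAL image's profiles, not
sequentially re-profiled after cropping one axis.

A degenerate axis (all-zero profile, or an empty retained set) falls back to
the full extent of that axis and sets ``fallback_used`` instead of raising,
so one pathological image cannot abort a batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from radnorm.errors import ContractError, DegenerateInputError
from radnorm.image_io import GrayImage

__all__ = [
    "CropSpec",
    "CropResult",
    "axis_profile",
    "mass_cdf",
    "percentile_window",
    "cdf_crop",
]

DEFAULT_X_BOUNDS = (0.05, 0.95)
DEFAULT_Y_BOUNDS = (0.15, 0.95)


@dataclass(frozen=True)
class CropSpec:
    """Mass-fraction bounds per axis (x = columns, y = rows)."""

    x_lo: float = DEFAULT_X_BOUNDS[0]
    x_hi: float = DEFAULT_X_BOUNDS[1]
    y_lo: float = DEFAULT_Y_BOUNDS[0]
    y_hi: float = DEFAULT_Y_BOUNDS[1]

    def __post_init__(self) -> None:
        for lo, hi, name in ((self.x_lo, self.x_hi, "x"), (self.y_lo, self.y_hi, "y")):
            if not (0.0 <= lo < hi <= 1.0):
                raise ContractError(
                    f"CropSpec {name}-bounds must satisfy 0 <= lo < hi <= 1, "
                    f"got ({lo}, {hi})"
                )


@dataclass(frozen=True)
class CropResult:
    """Resolved inclusive crop window and the cropped image."""

    window: tuple[int, int, int, int]  # (x_first, x_last, y_first, y_last)
    image: GrayImage
    fallback_used: bool

    def __post_init__(self) -> None:
        x0, x1, y0, y1 = self.window
        if x0 > x1 or y0 > y1:
            raise ContractError(f"invalid window {self.window}")
        if self.image.shape != (y1 - y0 + 1, x1 - x0 + 1):
            raise ContractError("cropped image does not match window extents")


def axis_profile(image: GrayImage, axis: str) -> np.ndarray:
    """Grayscale-sum projection of the image onto one axis.

    ``horizontal`` sums each column (length = width); ``vertical`` sums each
    row (length = height).  Either profile sums to the total intensity mass.
    """
    px = np.asarray(image.pixels, dtype=np.float64)
    if axis == "horizontal":
        return px.sum(axis=0)
    if axis == "vertical":
        return px.sum(axis=1)
    raise ContractError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def mass_cdf(profile: np.ndarray) -> np.ndarray:
    """Normalized cumulative mass of a non-negative profile.

    ``cdf[i] = sum(profile[:i+1]) / sum(profile)``; non-decreasing, last
    entry exactly 1 (the final cumulative sum divided by itself).
    """
    prof = np.asarray(profile, dtype=np.float64)
    if prof.ndim != 1 or prof.size == 0:
        raise ContractError("profile must be a non-empty 1-D vector")
    if (prof < 0).any():
        raise ContractError("profile entries must be non-negative")
    csum = np.cumsum(prof)
    total = csum[-1]
    if total <= 0:
        raise DegenerateInputError("all-zero profile has no mass CDF")
    return csum / total


def percentile_window(
    cdf: np.ndarray, lo: float, hi: float
) -> Optional[tuple[int, int]]:
    """Inclusive index window retaining exactly the indices with ``lo < cdf[i] <= hi``.

    Returns ``None`` when the retained set is empty (the fallback condition);
    callers decide whether to keep the full extent instead.
    """
    if not lo < hi:
        raise ContractError(f"need lo < hi, got ({lo}, {hi})")
    cdf = np.asarray(cdf, dtype=np.float64)
    retained = np.nonzero((cdf > lo) & (cdf <= hi))[0]
    if retained.size == 0:
        return None
    return int(retained[0]), int(retained[-1])


def cdf_crop(image: GrayImage, spec: CropSpec = CropSpec()) -> CropResult:
    """Crop an image to the mass-percentile window of each axis profile.

    The horizontal profile is bounded by ``(x_lo, x_hi)`` and the vertical
    profile by ``(y_lo, y_hi)``; the crop is the sub-grid of retained rows by
    retained columns.  A degenerate axis keeps its full extent and flags
    ``fallback_used``.
    """
    h, w = image.shape
    fallback = False

    def _axis_window(axis: str, lo: float, hi: float, size: int) -> tuple[int, int]:
        nonlocal fallback
        try:
            cdf = mass_cdf(axis_profile(image, axis))
        except DegenerateInputError:
            fallback = True
            return 0, size - 1
        win = percentile_window(cdf, lo, hi)
        if win is None:
            fallback = True
            return 0, size - 1
        return win

    x0, x1 = _axis_window("horizontal", spec.x_lo, spec.x_hi, w)
    y0, y1 = _axis_window("vertical", spec.y_lo, spec.y_hi, h)

    cropped = GrayImage(image.pixels[y0 : y1 + 1, x0 : x1 + 1], image.depth)
    return CropResult(window=(x0, x1, y0, y1), image=cropped, fallback_used=fallback)
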