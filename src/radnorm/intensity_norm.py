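"""Intensity normalization strategies for 8-bit grayscale radiographs.

Three families are provided:

* ``minmax_scale`` — fixed-range linear mapping of [0, 255] to [0, 1]
  (NOT per-image min/max, so constant images stay well defined).
* ``zscore_fit`` / ``zscore_apply`` — centering/scaling by the mean and
  population standard deviation pooled over ALL pixels of a dataset.
* ``histogram_standardize`` — per-image affine moment matching to fixed
  target statistics: ``(I - mu_orig) / sigma_orig * sigma_target + mu_target``
  with ``mu_orig``/``sigma_orig`` the per-image mean and population standard
  deviation.  The default targets are 0.4776 * 255 = 121.788 and
  0.2238 * 255 = 57.069 on the 8-bit scale.

``adaptive_normalize`` composes mass-CDF percentile cropping with histogram
standardization (statistics computed on the cropped region), an optional
bilinear resize, and quantization back to uint8.  ``ablation_variant``
exposes the crop-only and histogram-only partial pipelines.

Conventions (documented choices, isolated here):
  * population (divide-by-N) standard deviation throughout;
  * histogram-standardized output is clipped to [0, 255] (pre-clip values
    are available via ``clip=False``);
  * quantization rounds half away from zero after clipping;
  * resizing is corner-aligned separable bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from radnorm.errors import ContractError, DegenerateInputError
from radnorm.image_io import DatasetManifest, GrayImage
from radnorm.roi_crop import CropResult, CropSpec, cdf_crop

__all__ = [
    "TARGET_MU_FRACTION",
    "TARGET_SIGMA_FRACTION",
    "StandardizationParams",
    "DatasetStats",
    "NormalizationSpec",
    "minmax_scale",
    "zscore_fit",
    "zscore_apply",
    "histogram_standardize",
    "adaptive_normalize",
    "ablation_variant",
    "resize_bilinear",
    "quantize_uint8",
]

#: Fractional target statistics on the unit scale; multiplied by 255 these
#: give the default 8-bit targets 121.788 and 57.069.
TARGET_MU_FRACTION = 0.4776
TARGET_SIGMA_FRACTION = 0.2238

_METHODS = ("scaling", "zscore", "adaptive", "crop_only", "hist_only")


@dataclass(frozen=True)
class StandardizationParams:
    """Target moments of the histogram standardization, on the 8-bit scale."""

    mu_target: float = TARGET_MU_FRACTION * 255.0
    sigma_target: float = TARGET_SIGMA_FRACTION * 255.0

    def __post_init__(self) -> None:
        if self.sigma_target <= 0:
            raise ContractError("sigma_target must be positive")


@dataclass(frozen=True)
class DatasetStats:
    """Global dataset-level intensity statistics (pooled over all pixels)."""

    mu_global: float
    sigma_global: float
    n_images: int

    def __post_init__(self) -> None:
        if self.sigma_global < 0:
            raise ContractError("sigma_global must be >= 0")
        if self.n_images < 1:
            raise ContractError("n_images must be >= 1")


@dataclass(frozen=True)
class NormalizationSpec:
    """A normalization method tag plus the parameters it requires.

    ``crop_only`` and ``hist_only`` are the partial pipelines used in the
    ablation study; ``adaptive`` is their composition.
    """

    method: str
    crop: CropSpec = field(default_factory=CropSpec)
    standardize: StandardizationParams = field(default_factory=StandardizationParams)
    output_size: Optional[tuple[int, int]] = None  # (height, width)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ContractError(
                f"unknown method {self.method!r}; expected one of {_METHODS}"
            )


def minmax_scale(image: GrayImage) -> GrayImage:
    """Divide every pixel by 255 (fixed-range scaling to [0, 1])."""
    if image.depth != "uint8":
        raise ContractError(f"minmax_scale requires uint8 input, got {image.depth!r}")
    return GrayImage(image.pixels.astype(np.float64) / 255.0, "unit")


def zscore_fit(manifest: DatasetManifest) -> DatasetStats:
    """Pool the mean and population standard deviation over all pixels of all images."""
    if len(manifest) < 1:
        raise ContractError("zscore_fit needs at least one image")
    total = 0.0
    total_sq = 0.0
    n = 0
    for rec in manifest:
        px = rec.load().pixels.astype(np.float64)
        total += px.sum()
        total_sq += np.square(px).sum()
        n += px.size
    mu = total / n
    var = max(total_sq / n - mu * mu, 0.0)
    return DatasetStats(mu_global=mu, sigma_global=float(np.sqrt(var)), n_images=len(manifest))


def zscore_apply(image: GrayImage, stats: DatasetStats) -> GrayImage:
    """Map each pixel to ``(pixel - mu_global) / sigma_global``."""
    if stats.sigma_global <= 0:
        raise DegenerateInputError(
            "dataset has zero intensity variance; z-score is undefined"
        )
    out = (image.pixels.astype(np.float64) - stats.mu_global) / stats.sigma_global
    return GrayImage(out, "standardized")


def histogram_standardize(
    image: GrayImage,
    params: StandardizationParams = StandardizationParams(),
    clip: bool = True,
) -> GrayImage:
    """Affinely match the image's mean/standard deviation to the targets.

    Each pixel maps to ``(I - mu_orig) / sigma_orig * sigma_target +
    mu_target`` with per-image moments (population standard deviation).
    A constant image (``sigma_orig == 0``) maps every pixel to the target
    mean.  With ``clip=True`` (default) the result is clipped to [0, 255];
    pre-clip the output's mean and standard deviation equal the targets
    exactly.
    """
    px = image.pixels.astype(np.float64)
    mu = px.mean()
    sigma = px.std()  # population (ddof=0)
    if sigma == 0.0:
        out = np.full_like(px, params.mu_target)
    else:
        out = (px - mu) / sigma * params.sigma_target + params.mu_target
    if clip:
        out = np.clip(out, 0.0, 255.0)
    return GrayImage(out, "standardized")


def quantize_uint8(image: GrayImage) -> GrayImage:
    """Clip to [0, 255] and round half away from zero to uint8."""
    px = np.clip(image.pixels.astype(np.float64), 0.0, 255.0)
    return GrayImage(np.floor(px + 0.5).astype(np.uint8), "uint8")


def resize_bilinear(image: GrayImage, height: int, width: int) -> GrayImage:
    """Separable corner-aligned bilinear resize.

    Output sample ``i`` along an axis of source length ``L`` maps to source
    coordinate ``i * (L - 1) / (out - 1)`` (corners map to corners); a
    length-1 axis broadcasts.  Resizing to the same size is the identity.
    """
    if height < 1 or width < 1:
        raise ContractError("target dimensions must be >= 1")
    px = image.pixels
    if (height, width) == px.shape:
        return image
    out = _interp_axis(px.astype(np.float64), height, axis=0)
    out = _interp_axis(out, width, axis=1)
    if image.depth == "uint8":
        return quantize_uint8(GrayImage(out, "standardized"))
    return GrayImage(out, image.depth)


def _interp_axis(arr: np.ndarray, new_len: int, axis: int) -> np.ndarray:
    old_len = arr.shape[axis]
    if new_len == old_len:
        return arr
    if old_len == 1:
        return np.repeat(arr, new_len, axis=axis)
    if new_len == 1:
        # single sample sits at the axis midpoint
        pos = np.array([(old_len - 1) / 2.0])
    else:
        pos = np.arange(new_len) * (old_len - 1) / (new_len - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, old_len - 1)
    frac = pos - lo
    shape = [1] * arr.ndim
    shape[axis] = new_len
    f = frac.reshape(shape)
    return np.take(arr, lo, axis=axis) * (1.0 - f) + np.take(arr, hi, axis=axis) * f


def adaptive_normalize(
    image: GrayImage, spec: NormalizationSpec
) -> tuple[GrayImage, CropResult]:
    """Full adaptive pipeline: crop, standardize on the ROI, resize, quantize.

    Pipeline order: ``cdf_crop`` -> ``histogram_standardize`` (moments
    computed on the CROPPED region) -> optional resize to
    ``spec.output_size`` -> uint8 quantization.  Returns the quantized image
    together with the crop result for auditability.
    """
    if spec.method != "adaptive":
        raise ContractError(f"adaptive_normalize requires method='adaptive', got {spec.method!r}")
    if image.depth != "uint8":
        raise ContractError("adaptive_normalize requires uint8 input")
    crop = cdf_crop(image, spec.crop)
    out = histogram_standardize(crop.image, spec.standardize, clip=True)
    if spec.output_size is not None:
        out = resize_bilinear(out, *spec.output_size)
    return quantize_uint8(out), crop


def ablation_variant(image: GrayImage, spec: NormalizationSpec) -> GrayImage:
    """Partial pipelines for the ablation study.

    ``crop_only`` crops then resizes (pure selection, no intensity change
    beyond interpolation); ``hist_only`` standardizes the full frame then
    resizes.  Both return uint8 images.
    """
    if image.depth != "uint8":
        raise ContractError("ablation_variant requires uint8 input")
    if spec.method == "crop_only":
        crop = cdf_crop(image, spec.crop)
        out: GrayImage = crop.image
        if spec.output_size is not None:
            out = resize_bilinear(out, *spec.output_size)
        return out
    if spec.method == "hist_only":
        out = histogram_standardize(image, spec.standardize, clip=True)
        if spec.output_size is not None:
            out = resize_bilinear(out, *spec.output_size)
        return quantize_uint8(out)
    raise ContractError(
        f"ablation_variant handles 'crop_only'/'hist_only', got {spec.method!r}"
    )
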