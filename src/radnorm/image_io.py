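"""Grayscale image and dataset-manifest I/O.

Canonical in-memory contract: a :class:`GrayImage` wraps a 2-D numpy array in
row-major order with origin at the top-left — row index is the vertical axis
(y, increasing downward), column index the horizontal axis (x).  Three depth
tags are used throughout the package:

``uint8``
    integers in [0, 255] (the on-disk representation),
``unit``
    reals in [0, 1],
``standardized``
    unbounded reals (z-scored or clipped-real intermediate results).

PNG is the canonical output format; JPEG is read but never written (its
round trip is lossy).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from radnorm.errors import ContractError, InputError

__all__ = [
    "GrayImage",
    "ManifestRecord",
    "DatasetManifest",
    "read_gray",
    "write_gray",
    "read_manifest",
    "write_manifest",
]

#: ITU-R BT.601 luma weights used to collapse RGB inputs to one channel.
_LUMA = np.array([0.299, 0.587, 0.114])

_DEPTHS = ("uint8", "unit", "standardized")


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale intensity grid plus its depth tag.

    Parameters
    ----------
    pixels:
        2-D array, ``height x width``.
    depth:
        One of ``uint8``, ``unit``, ``standardized`` (see module docstring).
    """

    pixels: np.ndarray
    depth: str = "uint8"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ContractError(
                f"GrayImage requires a non-empty 2-D grid, got shape {px.shape}"
            )
        if self.depth not in _DEPTHS:
            raise ContractError(f"unknown depth {self.depth!r}; expected one of {_DEPTHS}")
        if self.depth == "uint8":
            if not np.issubdtype(px.dtype, np.integer):
                if not np.array_equal(px, np.round(px)):
                    raise ContractError("uint8 depth requires integer pixel values")
            if px.min() < 0 or px.max() > 255:
                raise ContractError("uint8 depth requires values in [0, 255]")
            px = px.astype(np.uint8)
        elif self.depth == "unit":
            px = px.astype(np.float64)
            if px.min() < 0.0 or px.max() > 1.0:
                raise ContractError("unit depth requires values in [0, 1]")
        else:
            px = px.astype(np.float64)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ManifestRecord:
    """One dataset entry: an image (by path or embedded), label and grouping keys."""

    path: Optional[str]
    label: int
    patient_id: str
    domain: str
    pixels: Optional[np.ndarray] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise InputError(f"label must be 0 or 1, got {self.label!r}")
        if self.path is None and self.pixels is None:
            raise InputError("record needs either a path or embedded pixels")

    def load(self) -> GrayImage:
        """Return the image, reading from disk if not embedded."""
        if self.pixels is not None:
            return GrayImage(self.pixels, "uint8")
        return read_gray(self.path)


@dataclass(frozen=True)
class DatasetManifest:
    """An ordered collection of :class:`ManifestRecord`."""

    records: tuple[ManifestRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        for rec in self.records:
            if not rec.patient_id:
                raise InputError("every record requires a patient_id")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(r.domain for r in self.records)

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(r.patient_id for r in self.records)

    def subset(self, indices: Sequence[int]) -> "DatasetManifest":
        return DatasetManifest(tuple(self.records[i] for i in indices))


def read_gray(path: str | Path) -> GrayImage:
    """Read a PNG/JPEG image as 8-bit grayscale.

    Multi-channel inputs are collapsed with the ITU-R BT.601 luma weights
    (0.299 R + 0.587 G + 0.114 B), so a channel-equal RGB pixel maps to its
    channel value.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("L",):
                arr = np.asarray(im)
            elif im.mode in ("LA", "RGBA", "P"):
                arr = _luma(np.asarray(im.convert("RGB")))
            elif im.mode == "RGB":
                arr = _luma(np.asarray(im))
            elif im.mode in ("I", "I;16", "F"):
                raise InputError(f"unsupported bit depth in {path}: mode {im.mode}")
            else:
                arr = _luma(np.asarray(im.convert("RGB")))
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise InputError(f"zero-sized or non-2D image: {path}")
    return GrayImage(arr.astype(np.uint8), "uint8")


def _luma(rgb: np.ndarray) -> np.ndarray:
    out = rgb.astype(np.float64) @ _LUMA
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def write_gray(image: GrayImage, path: str | Path) -> None:
    """Write a uint8 image as PNG (bit-exact round trip with :func:`read_gray`)."""
    if image.depth != "uint8":
        raise ContractError(
            f"write_gray requires uint8 depth, got {image.depth!r}; quantize first"
        )
    path = Path(path)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        raise ContractError("JPEG output is lossy; write PNG instead")
    Image.fromarray(image.pixels.astype(np.uint8), mode="L").save(path, format="PNG")


_MANIFEST_COLUMNS = ("path", "label", "patient_id", "domain")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a CSV manifest with header ``path,label,patient_id,domain``."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InputError(f"empty manifest: {path}")
        missing = [c for c in _MANIFEST_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise InputError(f"manifest {path} missing column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            raw = row["label"].strip()
            if raw not in ("0", "1"):
                raise InputError(f"{path} row {i}: label must be 0 or 1, got {raw!r}")
            records.append(
                ManifestRecord(
                    path=row["path"],
                    label=int(raw),
                    patient_id=row["patient_id"],
                    domain=row["domain"],
                )
            )
    if not records:
        raise InputError(f"manifest {path} contains no records")
    return DatasetManifest(tuple(records))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest CSV; round trip preserves records and order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for rec in manifest:
            if rec.path is None:
                raise InputError("cannot serialize a manifest with embedded-only images")
            writer.writerow([rec.path, rec.label, rec.patient_id, rec.domain])
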