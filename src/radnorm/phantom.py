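"""Deterministic synthetic chest-radiograph phantom generator.

Each phantom composites a crude frontal-radiograph anatomy on a dark
background: two bright lung ellipses, a central mediastinum band between
them, a bright shoulder/neck band across the top rows, and darker lateral
margins.  Abnormal images (label 1) additionally carry one or more bright
opacity disks inside a lung ellipse.  A per-domain transform

    pixel -> clip(contrast_gain * 255 * (pixel/255)**gamma
                  + brightness_offset + noise)

then simulates site-to-site acquisition differences (exposure curve, gain,
offset, sensor noise) that intensity standardization should cancel while the
lesion signal survives.

Geometry defaults are chosen so the default crop percentiles excise the
shoulder band (its rows sit above the 15% vertical mass cut) and keep both
lung ellipses.  All randomness flows from explicit seeds / generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from radnorm.errors import ContractError
from radnorm.image_io import DatasetManifest, GrayImage, ManifestRecord, write_gray, write_manifest

__all__ = [
    "DomainParams",
    "LungEllipse",
    "PhantomConfig",
    "default_config",
    "generate_phantom",
    "generate_dataset",
]


@dataclass(frozen=True)
class DomainParams:
    """Per-site acquisition transform parameters."""

    brightness_offset: float = 0.0
    contrast_gain: float = 1.0
    gamma: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.contrast_gain <= 0 or self.gamma <= 0:
            raise ContractError("contrast_gain and gamma must be positive")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LungEllipse:
    """One lung field: fractional center, fractional semi-axes, intensity."""

    center: tuple[float, float]  # (row_frac, col_frac)
    semi_axes: tuple[float, float]  # (row_frac, col_frac)
    intensity: float = 150.0


@dataclass(frozen=True)
class PhantomConfig:
    size: tuple[int, int] = (128, 128)  # (height, width)
    background: float = 60.0
    lungs: tuple[LungEllipse, LungEllipse] = (
        LungEllipse(center=(0.48, 0.32), semi_axes=(0.20, 0.13)),
        LungEllipse(center=(0.48, 0.68), semi_axes=(0.20, 0.13)),
    )
    mediastinum_intensity: float = 90.0
    mediastinum_halfwidth: float = 0.06  # fraction of width around center column
    shoulder_fraction: float = 0.04  # top rows occupied by the bright band
    shoulder_intensity: float = 150.0
    lateral_margin: float = 0.12  # fraction of width per side
    lateral_intensity: float = 20.0
    lesion_count: tuple[int, int] = (2, 4)  # inclusive range for label 1
    lesion_radius: tuple[int, int] = (8, 12)  # pixels, inclusive
    lesion_delta: float = 60.0
    domains: dict[str, DomainParams] = field(
        default_factory=lambda: {"site_a": DomainParams()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shoulder_fraction >= 0.15:
            raise ContractError(
                "shoulder_fraction must stay below the default y_lo=0.15 crop bound"
            )
        if not self.domains:
            raise ContractError("config needs at least one domain")


def default_config(
    size: tuple[int, int] = (128, 128), noise_sd: float = 0.0, seed: int = 0
) -> PhantomConfig:
    """Three-site config with strong brightness/gain/gamma shifts between domains."""
    return PhantomConfig(
        size=size,
        domains={
            "site_a": DomainParams(0.0, 1.0, 1.0, noise_sd),
            "site_b": DomainParams(30.0, 1.05, 0.97, noise_sd),
            "site_c": DomainParams(-20.0, 0.92, 1.03, noise_sd),
        },
        seed=seed,
    )


def _base_anatomy(config: PhantomConfig) -> np.ndarray:
    h, w = config.size
    img = np.full((h, w), config.background, dtype=np.float64)

    # lateral non-diagnostic margins
    margin = int(round(config.lateral_margin * w))
    if margin > 0:
        img[:, :margin] = config.lateral_intensity
        img[:, w - margin :] = config.lateral_intensity

    # mediastinum band between the lungs
    half = int(round(config.mediastinum_halfwidth * w))
    c0, c1 = w // 2 - half, w // 2 + half
    r0, r1 = int(0.20 * h), int(0.92 * h)
    img[r0:r1, max(c0, 0) : min(c1, w)] = config.mediastinum_intensity

    # lung fields
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for lung in config.lungs:
        cr, cc = lung.center[0] * (h - 1), lung.center[1] * (w - 1)
        ar, ac = lung.semi_axes[0] * h, lung.semi_axes[1] * w
        mask = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0
        img[mask] = lung.intensity

    # shoulder/neck band on top
    band = int(round(config.shoulder_fraction * h))
    if band > 0:
        img[:band, :] = config.shoulder_intensity
    return img


def lung_masks(config: PhantomConfig) -> list[np.ndarray]:
    """Boolean masks of the two lung ellipses (pre-domain-transform geometry)."""
    h, w = config.size
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    masks = []
    for lung in config.lungs:
        cr, cc = lung.center[0] * (h - 1), lung.center[1] * (w - 1)
        ar, ac = lung.semi_axes[0] * h, lung.semi_axes[1] * w
        masks.append(((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0)
    return masks


def _add_lesions(
    img: np.ndarray, config: PhantomConfig, rng: np.random.Generator
) -> np.ndarray:
    h, w = config.size
    n = int(rng.integers(config.lesion_count[0], config.lesion_count[1] + 1))
    masks = lung_masks(config)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    out = img.copy()
    for _ in range(n):
        lung = config.lungs[int(rng.integers(len(config.lungs)))]
        radius = int(rng.integers(config.lesion_radius[0], config.lesion_radius[1] + 1))
        # sample the disk center inside the ellipse, margin of one radius
        cr = lung.center[0] * (h - 1)
        cc = lung.center[1] * (w - 1)
        ar = max(lung.semi_axes[0] * h - radius, 1.0)
        ac = max(lung.semi_axes[1] * w - radius, 1.0)
        theta = rng.uniform(0, 2 * np.pi)
        rho = np.sqrt(rng.uniform())
        y = cr + rho * ar * np.sin(theta)
        x = cc + rho * ac * np.cos(theta)
        disk = (rows - y) ** 2 + (cols - x) ** 2 <= radius**2
        out[disk & (masks[0] | masks[1])] += config.lesion_delta
    return out


def _domain_transform(
    img: np.ndarray, params: DomainParams, rng: np.random.Generator
) -> np.ndarray:
    out = params.contrast_gain * 255.0 * np.power(img / 255.0, params.gamma)
    out = out + params.brightness_offset
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(np.round(out), 0, 255)


def generate_phantom(
    config: PhantomConfig,
    domain: str,
    label: int,
    rng: np.random.Generator,
) -> tuple[GrayImage, dict]:
    """Generate one phantom image for a domain and binary label.

    Deterministic given the generator state.  Label 1 adds at least one
    opacity disk inside a lung ellipse before the domain transform.
    """
    if domain not in config.domains:
        raise ContractError(f"unknown domain {domain!r}")
    if label not in (0, 1):
        raise ContractError("label must be 0 or 1")
    img = _base_anatomy(config)
    meta: dict = {"domain": domain, "label": label}
    if label == 1:
        img = _add_lesions(img, config, rng)
    img = _domain_transform(img, config.domains[domain], rng)
    return GrayImage(img.astype(np.uint8), "uint8"), meta


def generate_dataset(
    config: PhantomConfig,
    n_per_domain: int,
    class_balance: float = 0.5,
    seed: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
) -> DatasetManifest:
    """Generate a labelled multi-domain dataset.

    Class proportions within each domain match ``class_balance`` to rounding
    (``n_pos = round(balance * n)``).  Synthetic patient ids group 1-3
    consecutive images each, so patient-level splitting is non-trivial.
    With ``out_dir`` set, PNGs and ``manifest.csv`` are written there;
    otherwise images are embedded in the manifest records.
    """
    if n_per_domain < 2:
        raise ContractError("n_per_domain must be >= 2")
    if not 0.0 <= class_balance <= 1.0:
        raise ContractError("class_balance must lie in [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    records: list[ManifestRecord] = []
    patient_counter = 0
    for domain in config.domains:
        n_pos = int(round(class_balance * n_per_domain))
        labels = [1] * n_pos + [0] * (n_per_domain - n_pos)
        # group consecutive images into patients of 1-3 images
        assignment: list[int] = []
        while len(assignment) < n_per_domain:
            size = int(rng.integers(1, 4))
            assignment.extend([patient_counter] * size)
            patient_counter += 1
        assignment = assignment[:n_per_domain]

        for i, (label, pid) in enumerate(zip(labels, assignment)):
            image, _ = generate_phantom(config, domain, label, rng)
            patient_id = f"P{pid:05d}"
            if out_path is not None:
                fname = f"{domain}_{i:04d}.png"
                write_gray(image, out_path / fname)
                records.append(
                    ManifestRecord(
                        path=str(out_path / fname),
                        label=label,
                        patient_id=patient_id,
                        domain=domain,
                    )
                )
            else:
                records.append(
                    ManifestRecord(
                        path=None,
                        label=label,
                        patient_id=patient_id,
                        domain=domain,
                        pixels=image.pixels,
                    )
                )
    manifest = DatasetManifest(tuple(records))
    if out_path is not None:
        write_manifest(manifest, out_path / "manifest.csv")
    return manifest
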