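"""Synthetic lesion-image generator.

Produces RGB images of irregular, diffuse-bordered lesion blobs on a textured
skin-toned background, paired with exact binary ground-truth masks.  The mask
is defined by thresholding the *pre-blur* lesion field at half its peak, so
the label boundary is crisp and reproducible while the rendered appearance
stays ambiguous at the ``border_softness`` scale — border uncertainty is then
an emergent property for any segmentation model trained on these images.

A dataset is a directory of ``<stem>_image.png`` / ``<stem>_mask.png`` pairs
plus a ``manifest.csv`` with columns ``image_path, mask_path, is_positive``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, DatasetIOError

MANIFEST_NAME = "manifest.csv"

__all__ = [
    "ImageSample",
    "GeneratorParams",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass
class ImageSample:
    """An RGB image in [0,1] with its binary ground-truth mask."""

    image: np.ndarray  # H x W x 3 float in [0, 1]
    mask: np.ndarray  # H x W int in {0, 1}; 1 = lesion
    is_positive: bool

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ConfigurationError(
                "mask", f"mask shape {self.mask.shape} does not match image {self.image.shape[:2]}"
            )


@dataclass
class GeneratorParams:
    n_samples: int = 100
    positive_fraction: float = 0.8
    image_size: int = 128
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    border_softness: float = 3.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_radius_range is None:
            # scale default radii with the image so lesions stay desk-plausible
            r = self.image_size / 128.0
            self.lesion_radius_range = (8.0 * r, 24.0 * r)
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ConfigurationError("n_samples", "must be >= 0")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ConfigurationError("positive_fraction", "must be in [0, 1]")
        if self.image_size < 16:
            raise ConfigurationError("image_size", "must be >= 16")
        lo, hi = self.lesion_count_range
        if lo > hi or lo < 1:
            raise ConfigurationError("lesion_count_range", "must be a nonempty range with min >= 1")
        rlo, rhi = self.lesion_radius_range
        if rlo > rhi or rlo <= 0:
            raise ConfigurationError("lesion_radius_range", "must be a nonempty positive range")
        if self.border_softness < 0:
            raise ConfigurationError("border_softness", "must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd", "must be >= 0")


def _background(size: int, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Skin-toned background with smooth low-frequency texture plus pixel noise."""
    base = np.array([0.80, 0.58, 0.50], dtype=np.float64)
    img = np.empty((size, size, 3), dtype=np.float64)
    for c in range(3):
        texture = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 12.0)
        texture *= 0.35 / max(texture.std(), 1e-9)
        img[..., c] = base[c] * (1.0 + 0.15 * texture)
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return img


def _lesion_field(size: int, rng: np.random.Generator, radius: float) -> np.ndarray:
    """Radially decaying field of one irregular blob, peak 1 at the centre.

    The 0.5 level set sits at distance ``radius * rho(theta)`` where ``rho``
    is a bounded harmonic perturbation (|rho - 1| <= 0.25), keeping the blob
    area close to pi * radius**2.
    """
    margin = 2.0 * radius * 1.25
    lo = min(margin, size / 2.0 - 1)
    cy = rng.uniform(lo, size - lo)
    cx = rng.uniform(lo, size - lo)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    d = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    # bounded angular irregularity: sum of |amplitudes| <= 0.25
    n_harm = rng.integers(2, 5)
    amps = rng.uniform(0.03, 0.10, size=n_harm)
    amps *= min(1.0, 0.25 / amps.sum())
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    ks = rng.integers(2, 6, size=n_harm)
    rho = 1.0 + sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, ks, phases))
    u = d / (radius * rho)
    return np.clip(1.0 - 0.5 * u, 0.0, 1.0)  # 0.5 exactly at u == 1


def _render_sample(params: GeneratorParams, rng: np.random.Generator, positive: bool) -> ImageSample:
    size = params.image_size
    img = _background(size, rng, params.noise_sd)
    mask = np.zeros((size, size), dtype=np.int64)
    if positive:
        n_lesions = int(rng.integers(params.lesion_count_range[0], params.lesion_count_range[1] + 1))
        shift = np.array([-0.28, -0.34, -0.18])  # towards darker red
        for _ in range(n_lesions):
            radius = rng.uniform(*params.lesion_radius_range)
            f = _lesion_field(size, rng, radius)
            mask |= f > 0.5
            soft = gaussian_filter(f, sigma=params.border_softness)
            strength = rng.uniform(0.8, 1.2)
            img += soft[..., None] * shift[None, None, :] * strength
            # subtle internal texture so the lesion is not flat
            tex = gaussian_filter(rng.standard_normal((size, size)), sigma=3.0)
            img += (soft * tex * 0.03)[..., None]
    img = np.clip(img, 0.0, 1.0)
    return ImageSample(image=img.astype(np.float32), mask=mask, is_positive=bool(mask.any()))


def generate_dataset(params: GeneratorParams) -> list[ImageSample]:
    """Generate ``params.n_samples`` samples with a deterministic positive count.

    Exactly ``round(positive_fraction * n_samples)`` samples are positive; the
    order of positives/negatives is a seeded shuffle.  Identical params + seed
    give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_pos = int(round(params.positive_fraction * params.n_samples))
    flags = np.zeros(params.n_samples, dtype=bool)
    flags[:n_pos] = True
    rng.shuffle(flags)
    return [_render_sample(params, rng, bool(f)) for f in flags]


def write_dataset(samples: list[ImageSample], directory: str | Path) -> Path:
    """Write samples as 8-bit PNG pairs plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        stem = f"sample_{i:04d}"
        img_name, mask_name = f"{stem}_image.png", f"{stem}_mask.png"
        img8 = np.clip(np.rint(s.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(img8, mode="RGB").save(directory / img_name)
        Image.fromarray((s.mask * 255).astype(np.uint8), mode="L").save(directory / mask_name)
        rows.append((img_name, mask_name, int(s.is_positive)))
    manifest = directory / MANIFEST_NAME
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "mask_path", "is_positive"])
        writer.writerows(rows)
    return manifest


def _read_pair(directory: Path, img_name: str, mask_name: str) -> ImageSample:
    mask_path = directory / mask_name
    if not mask_path.exists():
        raise DatasetIOError(f"missing mask for image '{img_name}' (expected '{mask_name}')")
    image = np.asarray(Image.open(directory / img_name).convert("RGB"), dtype=np.float32) / 255.0
    mask = (np.asarray(Image.open(mask_path).convert("L")) > 127).astype(np.int64)
    return ImageSample(image=image, mask=mask, is_positive=bool(mask.any()))


def read_dataset(directory: str | Path) -> list[ImageSample]:
    """Read a dataset directory (via its manifest, or by pairing ``*_image.png``)."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    samples: list[ImageSample] = []
    if manifest.exists():
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                samples.append(_read_pair(directory, row["image_path"], row["mask_path"]))
        return samples
    image_files = sorted(directory.glob("*_image.png"))
    if not image_files:
        raise DatasetIOError(f"no manifest and no '*_image.png' files in {directory}")
    for img in image_files:
        samples.append(_read_pair(directory, img.name, img.name.replace("_image.png", "_mask.png")))
    return samples
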