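"""Synthetic CT-like nodule phantoms with ground-truth masks and class labels.

The generator emulates a single axial CT slice cropped around a pulmonary
nodule: a dark, homogeneous parenchyma background with a brighter nodule
blob, corrupted by additive Gaussian noise.  Benignity/malignancy is encoded
through the margin geometry — the dominant radiological cue the downstream
shape features target: a benign nodule has a smooth circular margin, a
malignant one a spiculated margin obtained by a sinusoidal radial
perturbation

    r(theta) = base_radius * (1 + amplitude * sin(lobes * theta + phi)),

with the phase ``phi`` drawn from the seeded RNG.  A sample is labelled
malignant iff its spiculation amplitude exceeds
:data:`MALIGNANCY_AMPLITUDE_THRESHOLD`.

Every sample carries its ground-truth mask, so each downstream stage
(denoising, segmentation, feature extraction, classification) is testable
without any external image data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidSpecError

#: Spiculation amplitude above which a phantom is labelled malignant.
MALIGNANCY_AMPLITUDE_THRESHOLD = 0.15

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic nodule slice.

    Attributes
    ----------
    image_size : (rows, cols) in pixels.
    background_level : parenchyma intensity in [0, 1].
    nodule_level : nodule intensity in [0, 1]; must exceed the background.
    nodule_center : (row, col); image centre when None.
    base_radius : mean nodule radius in pixels (>= 3).
    spiculation_amplitude : radial perturbation as a fraction of
        ``base_radius``, in [0, 1]; 0 gives an exact circle.
    spiculation_lobes : number of radial perturbation cycles.
    noise_sigma : standard deviation of the additive Gaussian noise.
    rng_seed : seed for the phase and noise draws.
    """

    image_size: tuple[int, int] = (128, 128)
    background_level: float = 0.2
    nodule_level: float = 0.65
    nodule_center: tuple[float, float] | None = None
    base_radius: float = 18.0
    spiculation_amplitude: float = 0.0
    spiculation_lobes: int = 8
    noise_sigma: float = 0.05
    rng_seed: int = 0

    def center(self) -> tuple[float, float]:
        if self.nodule_center is not None:
            return self.nodule_center
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)

    def validate(self) -> None:
        if not (0.0 <= self.background_level < self.nodule_level <= 1.0):
            raise InvalidSpecError(
                "require 0 <= background_level < nodule_level <= 1, got "
                f"{self.background_level} and {self.nodule_level}"
            )
        if self.base_radius < 3:
            raise InvalidSpecError(f"base_radius must be >= 3, got {self.base_radius}")
        if not (0.0 <= self.spiculation_amplitude <= 1.0):
            raise InvalidSpecError("spiculation_amplitude must lie in [0, 1]")
        if self.spiculation_lobes < 1:
            raise InvalidSpecError("spiculation_lobes must be >= 1")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        rows, cols = self.image_size
        if rows < 8 or cols < 8:
            raise InvalidSpecError("image must be at least 8x8 pixels")
        r_max = self.base_radius * (1.0 + self.spiculation_amplitude)
        cr, cc = self.center()
        if (cr - r_max < 0 or cc - r_max < 0
                or cr + r_max > rows - 1 or cc + r_max > cols - 1):
            raise InvalidSpecError(
                f"nodule of maximal radius {r_max:.1f} at {(cr, cc)} exceeds "
                f"the {rows}x{cols} image bounds"
            )


@dataclass(frozen=True)
class PhantomSample:
    """A generated slice: image, ground-truth mask and class label."""

    image: np.ndarray
    mask: np.ndarray
    label: str
    spec: PhantomSpec

    @property
    def is_malignant(self) -> bool:
        return self.label == "malignant"


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom slice from its specification.

    The mask is the star-shaped region ``radius(theta) <= r(theta)`` about
    the nodule centre; pixelation artefacts are removed by hole filling and
    retaining the largest 4-connected component, so the mask is always a
    single component without holes.  With ``noise_sigma == 0`` every mask
    pixel is exactly ``nodule_level`` and the rest exactly
    ``background_level``.  Identical spec (including seed) gives identical
    output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)

    rows, cols = spec.image_size
    cr, cc = spec.center()
    rr, ccc = np.mgrid[0:rows, 0:cols]
    dy = rr - cr
    dx = ccc - cc
    theta = np.arctan2(dy, dx)
    radius = np.hypot(dy, dx)
    boundary = spec.base_radius * (
        1.0 + spec.spiculation_amplitude
        * np.sin(spec.spiculation_lobes * theta + phase)
    )
    mask = radius <= boundary
    mask = ndimage.binary_fill_holes(mask, structure=_FOUR_CONN)
    labels, n = ndimage.label(mask, structure=_FOUR_CONN)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    else:
        mask = labels == 1

    image = np.where(mask, spec.nodule_level, spec.background_level).astype(np.float64)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
        image = np.clip(image, 0.0, 1.0)

    label = (
        "malignant"
        if spec.spiculation_amplitude > MALIGNANCY_AMPLITUDE_THRESHOLD
        else "benign"
    )
    return PhantomSample(image=image, mask=mask, label=label, spec=spec)


@dataclass(frozen=True)
class SpecRanges:
    """Uniform sampling intervals for dataset generation.

    Benign and malignant amplitude ranges are disjoint by default and sit on
    either side of :data:`MALIGNANCY_AMPLITUDE_THRESHOLD`, giving two classes
    whose shape-feature distributions (solidity, eccentricity) are separated
    but overlap in all intensity statistics.
    """

    base_radius: tuple[float, float] = (12.0, 22.0)
    benign_amplitude: tuple[float, float] = (0.0, 0.10)
    malignant_amplitude: tuple[float, float] = (0.25, 0.45)
    spiculation_lobes: tuple[int, int] = (6, 11)
    noise_sigma: tuple[float, float] = (0.05, 0.05)
    background_level: tuple[float, float] = (0.15, 0.25)
    nodule_level: tuple[float, float] = (0.60, 0.70)
    center_jitter: float = 8.0

    def validate(self) -> None:
        for name in ("base_radius", "benign_amplitude", "malignant_amplitude",
                     "spiculation_lobes", "noise_sigma", "background_level",
                     "nodule_level"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidSpecError(f"empty range for {name}: ({lo}, {hi})")
        if self.center_jitter < 0:
            raise InvalidSpecError("center_jitter must be >= 0")


def generate_dataset(
    n: int,
    malignant_fraction: float = 0.5,
    spec_ranges: SpecRanges | None = None,
    rng_seed: int = 0,
    image_size: tuple[int, int] = (128, 128),
) -> list[PhantomSample]:
    """Draw ``n`` phantoms with exactly ``round(n * malignant_fraction)``
    malignant samples, per-sample parameters uniform over ``spec_ranges``.

    The class sequence is a seeded shuffle, and each sample gets its own
    child seed, so a fixed ``rng_seed`` reproduces the dataset bitwise.
    """
    if n < 2:
        raise InvalidSpecError(f"need n >= 2 samples, got {n}")
    if not (0.0 < malignant_fraction < 1.0):
        raise InvalidSpecError("malignant_fraction must lie strictly in (0, 1)")
    ranges = spec_ranges if spec_ranges is not None else SpecRanges()
    ranges.validate()

    rng = np.random.default_rng(rng_seed)
    n_mal = int(round(n * malignant_fraction))
    is_mal = np.zeros(n, dtype=bool)
    is_mal[:n_mal] = True
    rng.shuffle(is_mal)

    samples: list[PhantomSample] = []
    for malignant in is_mal:
        amp_range = ranges.malignant_amplitude if malignant else ranges.benign_amplitude
        amplitude = rng.uniform(*amp_range)
        radius = rng.uniform(*ranges.base_radius)
        lobes = int(rng.integers(ranges.spiculation_lobes[0],
                                 ranges.spiculation_lobes[1] + 1))
        sigma = rng.uniform(*ranges.noise_sigma)
        bg = rng.uniform(*ranges.background_level)
        fg = rng.uniform(*ranges.nodule_level)
        jr, jc = rng.uniform(-ranges.center_jitter, ranges.center_jitter, size=2)
        center = ((image_size[0] - 1) / 2.0 + jr, (image_size[1] - 1) / 2.0 + jc)
        spec = PhantomSpec(
            image_size=image_size,
            background_level=bg,
            nodule_level=fg,
            nodule_center=center,
            base_radius=radius,
            spiculation_amplitude=amplitude,
            spiculation_lobes=lobes,
            noise_sigma=sigma,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        samples.append(generate_phantom(spec))
    return samples


def save_dataset(samples: Sequence[PhantomSample], out_dir: str | Path) -> Path:
    """Write samples as 8-bit grayscale PNGs plus a manifest CSV.

    Produces ``sample_XXXX.png`` / ``mask_XXXX.png`` pairs and
    ``manifest.csv`` with one row per sample (filename, label and every
    spec field).  Returns the manifest path.
    """
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i, s in enumerate(samples):
        img_name = f"sample_{i:04d}.png"
        mask_name = f"mask_{i:04d}.png"
        iio.imwrite(out / img_name, (np.clip(s.image, 0, 1) * 255).astype(np.uint8))
        iio.imwrite(out / mask_name, (s.mask.astype(np.uint8) * 255))
        rec = {"filename": img_name, "mask_filename": mask_name, "label": s.label}
        rec.update(dataclasses.asdict(s.spec))
        rec["image_size"] = f"{s.spec.image_size[0]}x{s.spec.image_size[1]}"
        cr, cc = s.spec.center()
        rec["nodule_center"] = f"{cr:.3f},{cc:.3f}"
        records.append(rec)
    manifest = out / "manifest.csv"
    pd.DataFrame.from_records(records).to_csv(manifest, index=False)
    return manifest
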