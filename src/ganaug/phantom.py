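"""Synthetic brain-MRI-like phantom images with class-conditional tumors.

Each phantom is a 2-D 8-bit grayscale image containing a bright elliptical
skull ring, a brain interior, and (optionally) one tumor blob whose position
follows the anatomical prior of its class: gliomas sit off-center in a
cerebral hemisphere, pituitary tumors sit inferior-central (the sella region),
and meningiomas sit peripherally, abutting the inner skull surface.  The three
prior regions are spatially disjoint, so a mean-intensity statistic inside
each region separates the classes — which is exactly what makes cohorts of
these phantoms usable as a fully controlled stand-in for a real
contrast-enhanced MRI collection when exercising the pipeline.

All randomness is driven by the spec seed: the same ``PhantomSpec`` always
renders the same bytes.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import ParameterError

TUMOR_CLASSES = ("glioma", "meningioma", "pituitary")
PLANES = ("sagittal", "coronal", "axial")

#: intensity added on top of the brain mean inside a tumor blob
TUMOR_OFFSET = 60.0
#: vertical squash of the skull ellipse relative to its horizontal semi-axis
RING_ASPECT = 0.9
#: brain fills this fraction of the inner skull radius; the rest is a dark
#: CSF-like gap that detaches the brain from the skull ring
BRAIN_FILL = 0.88
#: nominal normalized elliptical center offsets per class (unit = brain axis)
_CLASS_OFFSETS = {
    "glioma": (0.62, -0.10),      # hemispheric, mirrored left/right
    "pituitary": (0.0, 0.62),     # inferior-central (y axis points down)
    "meningioma": (0.0, -0.97),   # peripheral, superior, abutting the edge
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one rendered phantom; all intensities are gray levels."""

    image_size: int = 64
    ring_inner: float = 0.38   # inner skull radius as a fraction of image size
    ring_outer: float = 0.46   # outer skull radius as a fraction of image size
    brain_intensity: float = 110.0
    skull_intensity: float = 220.0
    tumor_class: str = "none"
    tumor_radius: float = 6.0
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.ring_inner < self.ring_outer <= 0.5):
            raise ParameterError(
                f"need 0 < ring_inner < ring_outer <= 0.5, got "
                f"({self.ring_inner}, {self.ring_outer})")
        if self.tumor_class not in TUMOR_CLASSES + ("none",):
            raise ParameterError(f"unknown tumor_class {self.tumor_class!r}")
        if self.tumor_radius < 0:
            raise ParameterError("tumor_radius must be >= 0")
        if (self.tumor_radius == 0) != (self.tumor_class == "none"):
            raise ParameterError("tumor_radius == 0 iff tumor_class == 'none'")
        for name in ("brain_intensity", "skull_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ParameterError(f"{name} must lie in [0, 255], got {v}")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.image_size < 16:
            raise ParameterError("image_size must be >= 16")
        # the tumor must fit inside the brain interior
        if self.tumor_radius > 0:
            ry = RING_ASPECT * BRAIN_FILL * self.ring_inner * self.image_size
            if self.tumor_radius + 1.0 >= ry:
                raise ParameterError("tumor_radius places the tumor outside the brain")


def _ellipse_dist(size: int, rx: float, ry: float) -> np.ndarray:
    """Normalized elliptical distance from the image center (1.0 = boundary)."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return np.sqrt(((xx - c) / rx) ** 2 + ((yy - c) / ry) ** 2)


def _brain_axes(spec: PhantomSpec) -> tuple[float, float]:
    rx = BRAIN_FILL * spec.ring_inner * spec.image_size
    return rx, RING_ASPECT * rx


def brain_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the brain interior (detached from the skull by a gap)."""
    rx, ry = _brain_axes(spec)
    return _ellipse_dist(spec.image_size, rx, ry) < 1.0


def skull_mask(spec: PhantomSpec) -> np.ndarray:
    s = spec.image_size
    rxo = spec.ring_outer * s
    rxi = spec.ring_inner * s
    d_out = _ellipse_dist(s, rxo, RING_ASPECT * rxo)
    d_in = _ellipse_dist(s, rxi, RING_ASPECT * rxi)
    return (d_out < 1.0) & (d_in >= 1.0)


def _max_center_norm(spec: PhantomSpec) -> float:
    """Largest normalized elliptical center offset keeping the blob inside
    the brain (conservative: bounds the blob by a circle of radius r+1)."""
    _, ry = _brain_axes(spec)
    return max(0.0, 1.0 - (spec.tumor_radius + 1.0) / ry)


def _nominal_center_norm(spec: PhantomSpec, tumor_class: str,
                         side: float = 1.0) -> tuple[float, float]:
    """Class-nominal normalized center, shrunk toward the center when the
    blob would not fit an image this small."""
    nx, ny = _CLASS_OFFSETS[tumor_class]
    nx *= side
    norm = float(np.hypot(nx, ny))
    cap = _max_center_norm(spec)
    if norm > cap:
        scale = cap / norm if norm > 0 else 0.0
        nx, ny = nx * scale, ny * scale
    return nx, ny


def class_prior_mask(spec: PhantomSpec, tumor_class: str) -> np.ndarray:
    """Boolean mask of the positional prior region for a tumor class.

    glioma: two mirror discs in the left/right hemispheres; pituitary: a disc
    inferior-central; meningioma: a peripheral superior wedge.  The regions
    are pairwise disjoint for the default geometry, which is what makes the
    per-region mean-intensity statistic a class separator.
    """
    if tumor_class not in TUMOR_CLASSES:
        raise ParameterError(f"no prior region for class {tumor_class!r}")
    s = spec.image_size
    c = (s - 1) / 2.0
    yy, xx = np.mgrid[0:s, 0:s]
    rx, ry = _brain_axes(spec)
    if tumor_class == "meningioma":
        norm = np.sqrt(((xx - c) / rx) ** 2 + ((yy - c) / ry) ** 2)
        cap = min(0.97, _max_center_norm(spec))
        band = (norm > cap - 0.35) & (norm < 1.0)
        angle = np.arctan2(c - yy, xx - c)  # y axis points down in images
        superior = (angle > np.deg2rad(50)) & (angle < np.deg2rad(130))
        return band & superior
    disc_r = 0.28 * rx
    out = np.zeros((s, s), dtype=bool)
    sides = (-1.0, 1.0) if tumor_class == "glioma" else (1.0,)
    for side in sides:
        nx, ny = _nominal_center_norm(spec, tumor_class, side)
        out |= np.hypot(xx - (c + nx * rx), yy - (c + ny * ry)) < disc_r
    return out


def _tumor_center(spec: PhantomSpec, rng: np.random.Generator) -> tuple[float, float]:
    s = spec.image_size
    c = (s - 1) / 2.0
    rx, ry = _brain_axes(spec)
    cap = _max_center_norm(spec)
    if spec.tumor_class == "meningioma":
        theta = rng.uniform(np.deg2rad(65), np.deg2rad(115))
        norm = min(0.97, cap)
        nx, ny = norm * np.cos(theta), -norm * np.sin(theta)
    else:
        side = float(rng.choice([-1.0, 1.0]))  # used by glioma only
        if spec.tumor_class == "pituitary":
            side = 1.0
        nx, ny = _nominal_center_norm(spec, spec.tumor_class, side)
        nx += rng.uniform(-0.04, 0.04)
        ny += rng.uniform(-0.04, 0.04)
        norm = float(np.hypot(nx, ny))
        if norm > cap and norm > 0:
            nx, ny = nx * cap / norm, ny * cap / norm
    return c + nx * rx, c + ny * ry


def _smooth_disk(size: int, cx: float, cy: float, radius: float) -> np.ndarray:
    """Gaussian-smoothed disk profile with support clipped back to the disk.

    Values below 0.5 are zeroed so the positive support stays at the disk
    boundary: the blob has a soft interior edge but its pixel count remains
    close to pi*r^2, which keeps area checks meaningful.
    """
    from scipy.ndimage import gaussian_filter

    yy, xx = np.mgrid[0:size, 0:size]
    disk = (np.hypot(xx - cx, yy - cy) <= radius).astype(float)
    prof = gaussian_filter(disk, sigma=0.8)
    prof[prof < 0.5] = 0.0
    return np.clip(prof, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, str]:
    """Render one phantom; returns (uint8 image, class label)."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    img = np.zeros((s, s), dtype=float)
    brain = brain_mask(spec)
    img[brain] = spec.brain_intensity
    img[skull_mask(spec)] = spec.skull_intensity

    if spec.tumor_class != "none":
        cx, cy = _tumor_center(spec, rng)
        prof = _smooth_disk(s, cx, cy, spec.tumor_radius)
        if (prof > 0).sum() and not brain[prof > 0].all():
            raise ParameterError("tumor extends outside the brain interior")
        img += TUMOR_OFFSET * prof
    else:
        rng.uniform()  # keep the stream aligned across classes

    if spec.noise_sigma > 0:
        from scipy.ndimage import gaussian_filter

        texture = gaussian_filter(rng.normal(0.0, spec.noise_sigma, (s, s)), sigma=2.0)
        img[brain] += 2.0 * texture[brain]
        img += rng.normal(0.0, spec.noise_sigma, (s, s))

    return np.clip(np.rint(img), 0, 255).astype(np.uint8), spec.tumor_class


def generate_cohort(n_per_class: dict[str, int], spec_template: PhantomSpec,
                    out_dir: str, seed: int):
    """Render a labeled cohort and return manifest records.

    Plane tags cycle through sagittal/coronal/axial.  Returns a list of
    ``(path, label, plane, split)`` records with split ``"unassigned"``;
    writing the CSV is the dataset module's job.
    """
    from .dataset import Manifest, Record

    for cls, n in n_per_class.items():
        if cls not in TUMOR_CLASSES + ("none",):
            raise ParameterError(f"unknown class {cls!r}")
        if n < 0:
            raise ParameterError("per-class counts must be >= 0")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    records = []
    idx = 0
    for cls in sorted(n_per_class):
        for i in range(n_per_class[cls]):
            sub = int(rng.integers(0, 2**31 - 1))
            spec = dataclasses.replace(
                spec_template, tumor_class=cls,
                tumor_radius=0.0 if cls == "none" else spec_template.tumor_radius,
                seed=sub)
            img, label = generate_phantom(spec)
            path = os.path.join(out_dir, f"{cls}_{i:04d}.png")
            Image.fromarray(img, mode="L").save(path)
            records.append(Record(path=path, label=label,
                                  plane=PLANES[idx % 3], split="unassigned"))
            idx += 1
    return Manifest(records)
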