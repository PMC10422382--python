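"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators, both pure functions of their spec and seed:

* :func:`make_planted_table` — a feature table where a known subset of
  columns carries class signal (class-specific means of magnitude
  ``class_sep``) and the rest are pure standard-normal noise. The planted
  index set is returned so selectors can be scored on recovery.

* :func:`make_synthetic_oct` — a directory-per-class tree of grayscale
  retinal-OCT-like B-scans: a dark vitreous above a bright, gently curved
  retinal band over a darker choroid, with one lesion archetype per
  disease class (drusen-like bumps for ARMD, hemilateral thickening for
  BRVO, diffuse thickening with scattered dark blobs for CRVO, a
  sub-band fluid dome for CSCR, intraretinal cystic blobs for DME) plus
  multiplicative speckle-like noise. These are stylized band-and-blob
  textures sufficient to exercise loaders, training loops and shape
  contracts — not anatomically faithful renders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .features import FeatureTable

__all__ = [
    "PlantedTableSpec",
    "SyntheticOCTSpec",
    "DEFAULT_CLASS_COUNTS",
    "make_planted_table",
    "make_synthetic_oct",
]

#: per-class image counts of the emulated clinical dataset, divided by 20
DEFAULT_CLASS_COUNTS = {"ARMD": 37, "BRVO": 22, "CRVO": 16, "CSCR": 37, "DME": 38}


@dataclass(frozen=True)
class PlantedTableSpec:
    n_per_class: int = 100
    n_classes: int = 5
    n_informative: int = 10
    n_noise: int = 90
    class_sep: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if self.n_informative + self.n_noise == 0:
            raise ValueError("need at least one feature")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def make_planted_table(spec: PlantedTableSpec) -> tuple[FeatureTable, np.ndarray]:
    """Planted-signal table; returns (table, sorted informative indices).

    Informative columns: per class c and column j the class mean is drawn
    once from N(0, class_sep^2); within-class spread is ``noise_sd``.
    Noise columns are iid standard normal regardless of class. Informative
    columns occupy seeded random positions among the d columns.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.n_informative + spec.n_noise
    n = spec.n_per_class * spec.n_classes
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)

    positions = rng.permutation(d)
    planted = np.sort(positions[: spec.n_informative])

    X = rng.standard_normal((n, d))
    class_means = spec.class_sep * rng.standard_normal(
        (spec.n_classes, spec.n_informative)
    )
    X[:, planted] = spec.noise_sd * X[:, planted] + class_means[labels]

    prov = {
        "generator": "planted_table",
        "seed": spec.seed,
        "class_sep": spec.class_sep,
        "noise_sd": spec.noise_sd,
        "planted_indices": planted.tolist(),
        "planted_class_means": class_means.tolist(),
    }
    return FeatureTable(X, labels, prov), planted


@dataclass(frozen=True)
class SyntheticOCTSpec:
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    image_size: tuple[int, int] | None = None  # (H, W); None = per-image draw
    height_range: tuple[int, int] = (300, 350)
    width_range: tuple[int, int] = (1000, 1050)
    seed: int = 0

    def __post_init__(self):
        if not self.class_counts:
            raise ValueError("class_counts must be nonempty")
        for cls, n in self.class_counts.items():
            if n <= 0:
                raise ValueError(f"class {cls!r} has non-positive count {n}")


def _band_profile(width: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth foveal-dip-like curve for the band's vertical center (0..1)."""
    x = np.linspace(0, 1, width)
    dip = 0.08 * np.exp(-((x - rng.uniform(0.4, 0.6)) ** 2) / 0.01)
    tilt = rng.uniform(-0.05, 0.05) * (x - 0.5)
    return 0.45 + tilt + dip


def _add_blobs(img: np.ndarray, rng, n_blobs, rows, intensity, radius):
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cy = int(rng.uniform(*rows) * h)
        cx = rng.integers(int(0.1 * w), int(0.9 * w))
        r = radius * rng.uniform(0.7, 1.3) * h
        mask = np.exp(-(((yy - cy) ** 2 + ((xx - cx) / 2.2) ** 2) / (2 * r * r)))
        img += intensity * mask


def _render_class(cls: str, h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    img = np.full((h, w), 0.08)
    img += 0.04 * np.linspace(0, 1, h)[:, None]  # choroid slightly brighter below

    center = _band_profile(w, rng)
    thickness = rng.uniform(0.10, 0.13)
    if cls == "BRVO":  # hemilateral thickening
        half = np.where(np.linspace(0, 1, w) < 0.5, 1.0, 0.0)
        if rng.random() < 0.5:
            half = 1.0 - half
        thickness = thickness * (1.0 + 1.2 * half)
    elif cls == "CRVO":  # diffuse thickening
        thickness = thickness * 2.0

    rows = np.arange(h)[:, None] / h
    band = np.exp(-((rows - center[None, :]) ** 2) / (2 * (thickness / 2) ** 2))
    img += 0.55 * band

    if cls == "ARMD":  # drusen: small bright bumps under the band
        _add_blobs(img, rng, rng.integers(6, 12),
                   (0.50, 0.60), 0.35, 0.012)
    elif cls == "CRVO":
        _add_blobs(img, rng, rng.integers(4, 8), (0.38, 0.55), -0.30, 0.02)
    elif cls == "CSCR":  # single dark serous dome beneath the band
        _add_blobs(img, rng, 1, (0.55, 0.62), -0.45, 0.06)
    elif cls == "DME":  # multiple intraretinal cysts
        _add_blobs(img, rng, rng.integers(5, 9), (0.40, 0.52), -0.35, 0.018)

    speckle = rng.gamma(shape=6.0, scale=1.0 / 6.0, size=(h, w))
    img = np.clip(img * speckle + 0.02 * rng.standard_normal((h, w)), 0, 1)
    return (img * 255).astype(np.uint8)


def make_synthetic_oct(spec: SyntheticOCTSpec, out_dir: str | Path) -> Path:
    """Write a seeded directory-per-class PNG tree; returns the root path."""
    out_dir = Path(out_dir)
    classes = sorted(spec.class_counts)
    for ci, cls in enumerate(classes):
        cdir = out_dir / cls
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(spec.class_counts[cls]):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, ci, i]))
            if spec.image_size is not None:
                h, w = spec.image_size
            else:
                h = int(rng.integers(spec.height_range[0], spec.height_range[1] + 1))
                w = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
            arr = _render_class(cls, h, w, rng)
            Image.fromarray(arr, mode="L").save(cdir / f"{cls.lower()}_{i:04d}.png")
    return out_dir
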