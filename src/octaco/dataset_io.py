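"""Directory-per-class image datasets: manifests and stratified splits.

A dataset lives on disk as ``root/<class_name>/<image>``. ``scan_dataset``
walks it into an :class:`ImageManifest`; ``split_manifest`` assigns each
record to the train or test partition with a seeded, stratified draw. The
per-class test count is ``round_half_up(test_fraction * class_total)``,
the rounding rule consistent with published per-class train/test tallies
for an 80:20 split (e.g. 738 -> 148 test / 590 train, 313 -> 63 / 250).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}

__all__ = [
    "ImageRecord",
    "ImageManifest",
    "SplitSpec",
    "round_half_up",
    "scan_dataset",
    "split_manifest",
    "save_manifest",
    "load_manifest",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (for positive x)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ImageRecord:
    path: Path
    class_name: str
    split: str = "unassigned"  # train | test | unassigned


@dataclass
class ImageManifest:
    records: list[ImageRecord]
    class_names: list[str]

    def __post_init__(self):
        known = set(self.class_names)
        for r in self.records:
            if r.class_name not in known:
                raise ValueError(f"record class {r.class_name!r} not in class_names")

    def __len__(self):
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_names}
        for r in self.records:
            counts[r.class_name] += 1
        return counts

    def subset(self, split: str) -> "ImageManifest":
        return ImageManifest(
            [r for r in self.records if r.split == split], list(self.class_names)
        )

    def labels(self) -> np.ndarray:
        """Integer labels in class_names order."""
        index = {c: i for i, c in enumerate(self.class_names)}
        return np.array([index[r.class_name] for r in self.records], dtype=np.int64)


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.20
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError(
                f"test_fraction must be in (0, 1), got {self.test_fraction}"
            )


def scan_dataset(root: str | Path, class_names: list[str] | None = None) -> ImageManifest:
    """Walk a directory-per-class tree into an unassigned manifest.

    ``class_names`` fixes the label order; if omitted, the lexicographically
    sorted subdirectory names are used. Non-image files are skipped with a
    logged warning. Raises if a class directory is missing or holds no images.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    if class_names is None:
        class_names = sorted(p.name for p in root.iterdir() if p.is_dir())
        if not class_names:
            raise ValueError(f"no class subdirectories under {root}")
    records: list[ImageRecord] = []
    for cls in class_names:
        cdir = root / cls
        if not cdir.is_dir():
            raise FileNotFoundError(f"missing class directory: {cdir}")
        n_before = len(records)
        for p in sorted(cdir.iterdir()):
            if not p.is_file():
                continue
            if p.suffix.lower() not in IMAGE_EXTENSIONS:
                logger.warning("skipping non-image file %s", p)
                continue
            records.append(ImageRecord(path=p, class_name=cls))
        if len(records) == n_before:
            raise ValueError(f"class directory {cdir} contains no images")
    return ImageManifest(records, list(class_names))


def split_manifest(m: ImageManifest, s: SplitSpec) -> ImageManifest:
    """Assign train/test splits, stratified per class, seeded.

    Per class, exactly ``round_half_up(test_fraction * class_total)`` records
    go to test; which ones is a uniform seeded draw. All records must be
    unassigned, and every class needs at least 2 images.
    """
    if any(r.split != "unassigned" for r in m.records):
        raise ValueError("manifest already has split assignments")
    counts = m.class_counts()
    for cls, n in counts.items():
        if n < 2:
            raise ValueError(f"class {cls!r} has {n} image(s); need at least 2 to split")
    rng = np.random.default_rng(s.seed)
    new_records = list(m.records)
    for cls in m.class_names:
        idx = [i for i, r in enumerate(m.records) if r.class_name == cls]
        n_test = round_half_up(s.test_fraction * len(idx))
        test_pos = set(rng.choice(len(idx), size=n_test, replace=False).tolist())
        for j, i in enumerate(idx):
            new_records[i] = replace(
                m.records[i], split="test" if j in test_pos else "train"
            )
    return ImageManifest(new_records, list(m.class_names))


def save_manifest(m: ImageManifest, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "class", "split"])
        for r in m.records:
            w.writerow([str(r.path), r.class_name, r.split])


def load_manifest(path: str | Path) -> ImageManifest:
    records = []
    classes: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["path", "class", "split"]:
            raise ValueError(f"unexpected manifest header: {header}")
        for row in reader:
            p, cls, split = row
            records.append(ImageRecord(Path(p), cls, split))
            if cls not in classes:
                classes.append(cls)
    return ImageManifest(records, sorted(classes))
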