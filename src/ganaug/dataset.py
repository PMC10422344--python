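"""Manifest handling, stratified splitting, class balancing, normalization.

The manifest CSV (header ``path,label,plane,split`` plus an optional
``origin`` column tagging synthetic rows) is the unit of I/O between all
pipeline stages.  Splitting is stratified per class at configurable
train/validation/test percentages; with the 60:20:20 default the per-class
rounding rule (train = floor, validation = round-half-up, test = remainder)
reproduces the published per-class counts of the 3064-image reference
collection exactly: 1426 -> 855/285/286, 708 -> 424/142/142, 930 ->
558/186/186.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

from .errors import (DataError, DegenerateInputError, FormatError,
                     InsufficientClassError, MisuseError, ParameterError)

REQUIRED_COLUMNS = ("path", "label", "plane", "split")
SPLITS = ("train", "validation", "test", "unassigned")


@dataclass(frozen=True)
class Record:
    path: str
    label: str
    plane: str
    split: str = "unassigned"
    origin: str = "real"


@dataclass
class Manifest:
    records: list[Record] = field(default_factory=list)

    def __post_init__(self):
        # oversampled rows (origin "duplicate") may legitimately repeat a path
        seen = set()
        for r in self.records:
            if r.origin != "duplicate":
                if r.path in seen:
                    raise FormatError(f"duplicate path in manifest: {r.path}")
                seen.add(r.path)
            if r.split not in SPLITS:
                raise FormatError(f"invalid split {r.split!r} for {r.path}")

    def __len__(self):
        return len(self.records)

    def __eq__(self, other):
        return isinstance(other, Manifest) and self.records == other.records

    @property
    def vocabulary(self) -> list[str]:
        return sorted({r.label for r in self.records})

    def subset(self, split: str) -> "Manifest":
        return Manifest([r for r in self.records if r.split == split])

    def class_counts(self, split: str | None = None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            if split is None or r.split == split:
                counts[r.label] = counts.get(r.label, 0) + 1
        return counts


@dataclass(frozen=True)
class SplitRatios:
    """Train/validation/test percentages; must sum to exactly 100."""

    train: float = 60.0
    validation: float = 20.0
    test: float = 20.0

    def __post_init__(self):
        for name in ("train", "validation", "test"):
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ParameterError(f"{name} ratio must lie in (0, 100), got {v}")
        if abs(self.train + self.validation + self.test - 100.0) > 1e-9:
            raise ParameterError("split ratios must sum to 100")

    @classmethod
    def parse(cls, text: str) -> "SplitRatios":
        parts = text.split(":")
        if len(parts) != 3:
            raise ParameterError(f"expected TRAIN:VAL:TEST, got {text!r}")
        return cls(*(float(p) for p in parts))


def split_counts(n: int, ratios: SplitRatios) -> tuple[int, int, int]:
    """Per-class counts: train = floor, validation = round-half-up, test = rest."""
    n_train = math.floor(ratios.train * n / 100.0)
    n_val = math.floor(ratios.validation * n / 100.0 + 0.5)
    return n_train, n_val, n - n_train - n_val


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------


def read_manifest(path: str) -> Manifest:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"manifest {path} missing column(s): {', '.join(missing)}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(Record(
                    path=row["path"], label=row["label"], plane=row["plane"],
                    split=row["split"] or "unassigned",
                    origin=row.get("origin") or "real"))
            except FormatError:
                raise
            except Exception as exc:  # malformed row
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
    try:
        return Manifest(records)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_manifest(manifest: Manifest, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS + ("origin",))
        for r in manifest.records:
            writer.writerow([r.path, r.label, r.plane, r.split, r.origin])


def load_image(path: str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.uint8)


def save_image(img: np.ndarray, path: str) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path)


def resize_image(img: np.ndarray, res: int) -> np.ndarray:
    """Resize a square 2-D array: block-mean for integer downsampling,
    nearest-neighbour otherwise.  Values keep their scale."""
    a = np.asarray(img, dtype=float)
    h = a.shape[0]
    if h == res:
        return a
    if h > res and h % res == 0:
        f = h // res
        return a.reshape(res, f, res, f).mean(axis=(1, 3))
    idx = (np.arange(res) * h) // res
    return a[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_dataset(manifest: Manifest, ratios: SplitRatios, seed: int) -> Manifest:
    """Assign every record to train/validation/test, stratified per class."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(manifest.records):
        by_class.setdefault(r.label, []).append(i)
    assignment: dict[int, str] = {}
    for cls in sorted(by_class):
        idx = by_class[cls]
        if len(idx) < 3:
            raise InsufficientClassError(
                f"class {cls!r} has {len(idx)} samples; need >= 3 to split")
        n_train, n_val, _ = split_counts(len(idx), ratios)
        order = rng.permutation(len(idx))
        for rank, j in enumerate(order):
            if rank < n_train:
                split = "train"
            elif rank < n_train + n_val:
                split = "validation"
            else:
                split = "test"
            assignment[idx[j]] = split
    return Manifest([replace(r, split=assignment[i])
                     for i, r in enumerate(manifest.records)])


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------


def balance_by_oversampling(manifest: Manifest, target_split: str = "train",
                            mode: str = "duplicate", k: int = 5, seed: int = 0,
                            out_dir: str | None = None):
    """Oversample minority classes of the train split up to the majority count.

    ``duplicate`` resamples existing rows with replacement; ``smote``
    interpolates each synthetic image between a minority sample and one of its
    ``k`` nearest same-class neighbours in flattened-pixel space and writes it
    as a new file.  Returns ``(manifest, parent_log)`` where ``parent_log``
    lists ``(synthetic_path, parent_path, neighbour_path)`` for every image
    SMOTE created, so interpolation can be audited.
    """
    if target_split != "train":
        raise MisuseError("oversampling may only be applied to the train split")
    if mode not in ("duplicate", "smote"):
        raise ParameterError(f"unknown balance mode {mode!r}")
    counts = manifest.class_counts("train")
    if not counts:
        raise DataError("manifest has no train records")
    if any(c < 1 for c in counts.values()):
        raise DataError("every class needs at least one train sample")
    target = max(counts.values())
    rng = np.random.default_rng(seed)
    new_records: list[Record] = []
    parent_log: list[tuple[str, str, str]] = []
    for cls in sorted(counts):
        deficit = target - counts[cls]
        if deficit == 0:
            continue
        rows = [r for r in manifest.records if r.split == "train" and r.label == cls]
        use_smote = mode == "smote" and len(rows) >= 2
        if use_smote:
            if out_dir is None:
                raise ParameterError("smote mode needs out_dir for synthetic images")
            os.makedirs(out_dir, exist_ok=True)
            imgs = np.stack([load_image(r.path).astype(float) for r in rows])
            flat = imgs.reshape(len(rows), -1)
            # pairwise distances in flattened-pixel space
            d2 = ((flat[:, None, :] - flat[None, :, :]) ** 2).sum(axis=2)
            np.fill_diagonal(d2, np.inf)
            k_eff = min(k, len(rows) - 1)
            nn_idx = np.argsort(d2, axis=1)[:, :k_eff]
        for j in range(deficit):
            i = int(rng.integers(0, len(rows)))
            if use_smote:
                nb = int(nn_idx[i, int(rng.integers(0, k_eff))])
                u = float(rng.uniform(0.0, 1.0))
                synth = imgs[i] + u * (imgs[nb] - imgs[i])
                # quantize without leaving the parents' pixel-wise interval
                synth = np.clip(np.rint(synth), np.minimum(imgs[i], imgs[nb]),
                                np.maximum(imgs[i], imgs[nb]))
                path = os.path.join(out_dir, f"smote_{cls}_{j:04d}.png")
                save_image(synth, path)
                new_records.append(Record(path=path, label=cls,
                                          plane=rows[i].plane, split="train",
                                          origin="smote"))
                parent_log.append((path, rows[i].path, rows[nb].path))
            else:
                src = rows[i]
                # duplicate rows reference the existing file
                new_records.append(replace(src, origin="duplicate",
                                           path=src.path))
    if not new_records:
        return manifest, parent_log
    return Manifest(list(manifest.records) + new_records), parent_log


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize(img: np.ndarray, scheme: str = "minmax") -> np.ndarray:
    """Map an image to model range: minmax -> [0, 1], zscore -> mean 0 / sd 1."""
    x = np.asarray(img, dtype=float)
    if scheme == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    if scheme == "zscore":
        sd = x.std()
        if sd == 0:
            raise DegenerateInputError("zscore undefined for a constant image")
        return (x - x.mean()) / sd
    raise ParameterError(f"unknown normalization scheme {scheme!r}")
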