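"""Core record types and manifest I/O.

A dataset is a list of :class:`ImageRecord` plus a CSV manifest. Images are
stored as 2-D float arrays in [0, 1] in memory and as 8-bit grayscale PNG on
disk. The manifest schema is fixed: ``record_id, patient_id, eye, label,
provenance, parent_ids, path`` (parent ids semicolon-joined, UTF-8, header
row required).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

EYES = ("OD", "OS")
LABELS = ("AUTOSOMAL", "X_LINKED")
PROVENANCES = ("REAL", "SYNTHETIC_GEN1", "SYNTHETIC_GEN2")

MANIFEST_COLUMNS = [
    "record_id",
    "patient_id",
    "eye",
    "label",
    "provenance",
    "parent_ids",
    "path",
]


class ValidationError(ValueError):
    """Raised when a record, config, or manifest violates its contract."""


@dataclass
class ImageRecord:
    """One labeled image with patient/eye/laterality/provenance metadata.

    ``pixels`` is a 2-D (or 3-D channel-last) float array with values in
    [0, 1]. Provenance constrains ``parent_ids``: a REAL record has none, a
    GEN1 synthetic has exactly one parent, a GEN2 synthetic exactly two.
    """

    record_id: str
    patient_id: str
    eye: str
    label: str
    pixels: np.ndarray
    provenance: str = "REAL"
    parent_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValidationError(f"eye must be one of {EYES}, got {self.eye!r}")
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        n_parents = {"REAL": 0, "SYNTHETIC_GEN1": 1, "SYNTHETIC_GEN2": 2}[self.provenance]
        if len(self.parent_ids) != n_parents:
            raise ValidationError(
                f"{self.provenance} record must have {n_parents} parent(s), "
                f"got {len(self.parent_ids)}"
            )
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim not in (2, 3):
            raise ValidationError("pixels must be a 2-D or 3-D array")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValidationError(f"pixel values must lie in [0, 1], got [{lo}, {hi}]")
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    def with_pixels(self, pixels: np.ndarray, **meta) -> "ImageRecord":
        """Copy of this record with new pixels and extra meta entries."""
        return ImageRecord(
            record_id=self.record_id,
            patient_id=self.patient_id,
            eye=self.eye,
            label=self.label,
            pixels=pixels,
            provenance=self.provenance,
            parent_ids=list(self.parent_ids),
            meta={**self.meta, **meta},
        )


@dataclass
class LatentCode:
    """Gaussian posterior parameters for one encoded image."""

    mean: np.ndarray
    log_var: np.ndarray
    source_record_id: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.log_var = np.asarray(self.log_var, dtype=np.float64).ravel()
        if self.mean.shape != self.log_var.shape:
            raise ValidationError("mean and log_var must have the same length")
        if not (np.isfinite(self.mean).all() and np.isfinite(self.log_var).all()):
            raise ValidationError("latent code entries must be finite")

    def __len__(self) -> int:
        return self.mean.size


def pixels_to_png(pixels: np.ndarray, path: Path) -> None:
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    img8 = np.round(arr * 255.0).astype(np.uint8)
    Image.fromarray(img8, mode="L" if img8.ndim == 2 else "RGB").save(path, format="PNG")


def png_to_pixels(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float32)
    return arr / 255.0


def save_dataset(records: list[ImageRecord], out_dir: str | Path) -> Path:
    """Write PNGs plus manifest.csv under ``out_dir``; returns manifest path."""
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    images_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for rec in records:
            rel = Path("images") / f"{rec.record_id}.png"
            pixels_to_png(rec.pixels, out_dir / rel)
            writer.writerow(
                [
                    rec.record_id,
                    rec.patient_id,
                    rec.eye,
                    rec.label,
                    rec.provenance,
                    ";".join(rec.parent_ids),
                    str(rel),
                ]
            )
    return manifest_path


def load_dataset(manifest_path: str | Path) -> list[ImageRecord]:
    """Read a manifest CSV and its images back into ImageRecords."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    records: list[ImageRecord] = []
    with open(manifest_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            parents = [p for p in row["parent_ids"].split(";") if p]
            records.append(
                ImageRecord(
                    record_id=row["record_id"],
                    patient_id=row["patient_id"],
                    eye=row["eye"],
                    label=row["label"],
                    pixels=png_to_pixels(base / row["path"]),
                    provenance=row["provenance"],
                    parent_ids=parents,
                )
            )
    return records
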