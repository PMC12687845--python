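"""Image harmonization: laterality flip, resize, quality gating.

Right-eye (OD) photographs are horizontally mirrored so every image shares
the left-eye (OS) orientation before any encoding or training. Resizing is
bilinear. Manual quality review is modeled as a pluggable predicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from PIL import Image

from .records import ImageRecord, ValidationError


@dataclass
class PreprocessConfig:
    target_side: int = 224
    flip_od_to_os: bool = True
    quality_filter: str | None = None

    def __post_init__(self) -> None:
        if self.target_side < 16:
            raise ValidationError("target_side must be >= 16")


def harmonize_laterality(record: ImageRecord, config: PreprocessConfig | None = None) -> ImageRecord:
    """Mirror OD images about the vertical axis; OS images pass through.

    The flip is recorded in ``meta['flipped']`` and applied at most once
    per record (a second call on an already-flipped record is a no-op).
    """
    config = config or PreprocessConfig()
    if record.eye not in ("OD", "OS"):
        raise ValidationError(f"record {record.record_id} has no valid eye metadata")
    if record.eye == "OS" or not config.flip_od_to_os or record.meta.get("flipped"):
        return record
    return record.with_pixels(record.pixels[:, ::-1].copy(), flipped=True)


def flip_horizontal(record: ImageRecord) -> ImageRecord:
    """Unconditional horizontal mirror (involution; used for testing)."""
    return record.with_pixels(record.pixels[:, ::-1].copy())


def resize_pixels(pixels: np.ndarray, target_side: int) -> np.ndarray:
    if target_side < 16:
        raise ValidationError("target_side must be >= 16")
    arr = np.asarray(pixels, dtype=np.float32)
    if arr.size == 0:
        raise ValidationError("cannot resize empty pixels")
    if arr.shape[:2] == (target_side, target_side):
        return arr.copy()

    def _resize_plane(plane: np.ndarray) -> np.ndarray:
        im = Image.fromarray(plane, mode="F")
        out = im.resize((target_side, target_side), resample=Image.BILINEAR)
        return np.asarray(out, dtype=np.float32)

    if arr.ndim == 2:
        out = _resize_plane(arr)
    else:
        out = np.stack([_resize_plane(arr[:, :, c]) for c in range(arr.shape[2])], axis=2)
    return np.clip(out, 0.0, 1.0)


def resize_image(record: ImageRecord, target_side: int) -> ImageRecord:
    """Bilinear resize to ``target_side`` square; values clipped to [0, 1]."""
    return record.with_pixels(resize_pixels(record.pixels, target_side))


def apply_quality_gate(
    records: Sequence[ImageRecord],
    predicate: Callable[[ImageRecord], bool] | None = None,
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Partition records into (kept, excluded) by a pure predicate.

    Default predicate keeps everything, mirroring a manual review in which
    all images passed. Order is preserved on both sides.
    """
    if predicate is None:
        predicate = lambda r: True  # noqa: E731
    kept, excluded = [], []
    for rec in records:
        (kept if predicate(rec) else excluded).append(rec)
    return kept, excluded


def deduplicate_most_recent(
    records: Sequence[ImageRecord], date_key: str = "date"
) -> list[ImageRecord]:
    """Keep one record per (patient_id, eye): the most recent by meta date.

    Records without a date compare as oldest; ties keep the last seen.
    Models a most-recent-imaging-date curation rule at manifest level.
    """
    best: dict[tuple[str, str], ImageRecord] = {}
    for rec in records:
        key = (rec.patient_id, rec.eye)
        if key not in best or str(rec.meta.get(date_key, "")) >= str(
            best[key].meta.get(date_key, "")
        ):
            best[key] = rec
    order = {id(r): i for i, r in enumerate(records)}
    return sorted(best.values(), key=lambda r: order[id(r)])


def preprocess_dataset(
    records: Sequence[ImageRecord],
    config: PreprocessConfig | None = None,
    predicate: Callable[[ImageRecord], bool] | None = None,
) -> list[ImageRecord]:
    """Quality-gate, flip OD to OS orientation, and resize a whole dataset."""
    config = config or PreprocessConfig()
    kept, _ = apply_quality_gate(records, predicate)
    out = []
    for rec in kept:
        rec = harmonize_laterality(rec, config)
        if rec.side != config.target_side:
            rec = resize_image(rec, config.target_side)
        out.append(rec)
    return out
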