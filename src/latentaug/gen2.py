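"""Pairwise combinatorial latent expansion (Gen 2).

Every unordered pair of same-label training images contributes synthetic
images formed by linearly combining their latent codes,

    z_mix = r * z_a + (1 - r) * z_b,

at mixing ratios drawn from {0.1, 0.3, 0.5, 0.7, 0.9}, and decoding the
mixture. In the default ``single`` mode each of the C(n, 2) pairs within a
class emits one synthetic at a ratio drawn uniformly from the ratio set,
giving exactly C(n, 2) synthetics per class; ``all`` mode emits every
ratio for every pair, giving |ratios| * C(n, 2).

Mixing is restricted to pairs sharing a label; self-pairs are excluded
(they reconstruct the parent and add no diversity), and the symmetric
identity mix(a, b, r) = mix(b, a, 1 - r) makes ordered pairs redundant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .records import ImageRecord, ValidationError

DEFAULT_RATIOS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class MixSpec:
    parent_a: str
    parent_b: str
    ratio: float
    label: str

    def __post_init__(self) -> None:
        if self.parent_a == self.parent_b:
            raise ValidationError("parents of a mix must be distinct records")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValidationError("ratio must lie in [0, 1]")


def enumerate_pairs(
    records: Sequence[ImageRecord], label: str
) -> list[tuple[ImageRecord, ImageRecord]]:
    """All C(n, 2) unordered same-label pairs in canonical record_id order.

    A class with fewer than two records yields no pairs (warning, not
    error — the class is skipped).
    """
    members = sorted((r for r in records if r.label == label), key=lambda r: r.record_id)
    if len(members) < 2:
        warnings.warn(f"label {label!r} has {len(members)} record(s); no pairs emitted")
        return []
    return list(combinations(members, 2))


def mix_latents(z_a: np.ndarray, z_b: np.ndarray, r: float) -> np.ndarray:
    """Exact convex combination r * z_a + (1 - r) * z_b."""
    z_a = np.asarray(z_a, dtype=np.float64).ravel()
    z_b = np.asarray(z_b, dtype=np.float64).ravel()
    if z_a.shape != z_b.shape:
        raise ValidationError("latent vectors must have equal length")
    if not 0.0 <= r <= 1.0:
        raise ValidationError(f"ratio must lie in [0, 1], got {r}")
    return r * z_a + (1.0 - r) * z_b


def expand_gen2(
    records: Sequence[ImageRecord],
    codec,
    ratios: Sequence[float] = DEFAULT_RATIOS,
    seed: int = 0,
    mode: str = "single",
) -> list[ImageRecord]:
    """Pairwise combinatorial expansion over every same-label pair.

    mode='single': one synthetic per pair at a ratio drawn uniformly from
    ``ratios`` (C(n,2) synthetics per class). mode='all': one synthetic
    per (pair, ratio) combination. Synthetics carry provenance
    SYNTHETIC_GEN2, both parent ids, and the shared label.
    """
    records = list(records)
    ratios = tuple(float(r) for r in ratios)
    if not ratios:
        raise ValidationError("ratio set must be nonempty")
    if any(not 0.0 < r < 1.0 for r in ratios):
        raise ValidationError("ratios must lie strictly inside (0, 1)")
    if mode not in ("single", "all"):
        raise ValidationError("mode must be 'single' or 'all'")
    latents = {r.record_id: codec.encode(r.pixels, r.record_id) for r in records}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E2]))
    synthetics = []
    for label in sorted({r.label for r in records}):
        for rec_a, rec_b in enumerate_pairs(records, label):
            chosen = ratios if mode == "all" else (ratios[rng.integers(0, len(ratios))],)
            for r in chosen:
                z = mix_latents(latents[rec_a.record_id].mean, latents[rec_b.record_id].mean, r)
                pixels = codec.decode(z)
                synthetics.append(
                    ImageRecord(
                        record_id=f"mix_{rec_a.record_id}_{rec_b.record_id}_r{r:.2f}",
                        patient_id=f"{rec_a.patient_id}+{rec_b.patient_id}",
                        eye=rec_a.eye,
                        label=label,
                        pixels=pixels,
                        provenance="SYNTHETIC_GEN2",
                        parent_ids=[rec_a.record_id, rec_b.record_id],
                        meta={"ratio": r},
                    )
                )
    return records + synthetics
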