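"""Random-noise latent expansion (Gen 1).

Each real training image contributes exactly one synthetic image: its
latent embedding is perturbed by one of four noise schemes — constant,
Gaussian, uniform, or sinusoidal — chosen uniformly at random, with a
strength parameter drawn from Uniform(0.05, 1), and decoded back to pixel
space. The result is a two-fold expansion of the training set.

Noise is scaled per latent dimension by sigma_ref, the empirical standard
deviation of the training latents, so a given strength produces comparable
displacement under every scheme:

    CONSTANT:   eps_i = s * c * sigma_ref_i,      c ~ Uniform(-1, 1), one draw
    GAUSSIAN:   eps_i ~ Normal(0, (s * sigma_ref_i)^2), independent
    UNIFORM:    eps_i ~ Uniform(-s * sigma_ref_i, +s * sigma_ref_i), independent
    SINUSOIDAL: eps_i = s * sigma_ref_i * sin(2 pi f i / d + phi),
                f ~ Uniform{1..floor(d/2)}, phi ~ Uniform(0, 2 pi), one draw
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import ImageRecord, LatentCode, ValidationError

SCHEMES = ("CONSTANT", "GAUSSIAN", "UNIFORM", "SINUSOIDAL")
STRENGTH_RANGE = (0.05, 1.0)
_SCALE_FLOOR = 1e-6


@dataclass
class NoiseSpec:
    scheme: str
    strength: float
    seed: int
    scale_ref: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValidationError(f"scheme must be one of {SCHEMES}")
        lo, hi = STRENGTH_RANGE
        if not lo <= self.strength <= hi:
            raise ValidationError(f"strength must lie in [{lo}, {hi}], got {self.strength}")
        if self.scale_ref is not None:
            self.scale_ref = np.asarray(self.scale_ref, dtype=np.float64).ravel()
            if np.any(self.scale_ref <= 0):
                raise ValidationError("scale_ref entries must be > 0")


def estimate_latent_scale(latents: Sequence[LatentCode]) -> np.ndarray:
    """Per-dimension sample SD of latent means, floored at 1e-6."""
    if len(latents) < 2:
        raise ValidationError("need at least 2 latents to estimate scale")
    means = np.stack([lc.mean for lc in latents])
    sd = means.std(axis=0, ddof=1)
    return np.maximum(sd, _SCALE_FLOOR)


def sample_noise(spec: NoiseSpec, d: int) -> np.ndarray:
    """Draw one noise vector of length d according to the spec's scheme."""
    sigma = spec.scale_ref
    if sigma is None:
        sigma = np.ones(d)
    if sigma.size != d:
        raise ValidationError(f"scale_ref length {sigma.size} != d {d}")
    rng = np.random.default_rng(spec.seed)
    s = spec.strength
    if spec.scheme == "CONSTANT":
        c = rng.uniform(-1.0, 1.0)
        return s * c * sigma
    if spec.scheme == "GAUSSIAN":
        return rng.normal(0.0, s * sigma)
    if spec.scheme == "UNIFORM":
        return rng.uniform(-s * sigma, s * sigma)
    # SINUSOIDAL
    f = rng.integers(1, max(d // 2, 1) + 1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(d)
    return s * sigma * np.sin(2.0 * np.pi * f * i / d + phi)


def expand_gen1(
    records: Sequence[ImageRecord],
    codec,
    seed: int = 0,
) -> list[ImageRecord]:
    """Two-fold expansion: originals plus one noise-perturbed synthetic each.

    For every record, a scheme is chosen uniformly from the four and a
    strength from Uniform(0.05, 1); the synthetic image is
    ``decode(encode(x).mean + eps)``. Synthetics carry provenance
    SYNTHETIC_GEN1, one parent, and the parent's label. Deterministic
    given ``seed``.
    """
    records = list(records)
    if not records:
        raise ValidationError("expand_gen1 needs a nonempty record list")
    latents = [codec.encode(r.pixels, r.record_id) for r in records]
    if len(latents) >= 2:
        sigma_ref = estimate_latent_scale(latents)
    else:
        sigma_ref = np.ones(len(latents[0]))
    d = len(latents[0])
    master = np.random.SeedSequence([seed, 0x6E1])
    draw_rng = np.random.default_rng(master)
    synthetics = []
    for rec, lc in zip(records, latents):
        scheme = SCHEMES[draw_rng.integers(0, 4)]
        strength = draw_rng.uniform(*STRENGTH_RANGE)
        noise_seed = int(draw_rng.integers(0, 2**31 - 1))
        spec = NoiseSpec(scheme=scheme, strength=strength, seed=noise_seed, scale_ref=sigma_ref)
        eps = sample_noise(spec, d)
        pixels = codec.decode(lc.mean + eps)
        synthetics.append(
            ImageRecord(
                record_id=f"{rec.record_id}_g1",
                patient_id=rec.patient_id,
                eye=rec.eye,
                label=rec.label,
                pixels=pixels,
                provenance="SYNTHETIC_GEN1",
                parent_ids=[rec.record_id],
                meta={"scheme": scheme, "strength": strength},
            )
        )
    return records + synthetics
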