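"""Synthetic labeled fundus-like fixture datasets.

Generates small grayscale images with the statistical structure of a
retinitis-pigmentosa style cohort: two inheritance-mode classes, 1-2 eyes
per patient with left/right laterality, a bright optic-nerve-head surrogate
offset toward the nasal side, a darker macula surrogate, curvilinear dark
vessel strokes, a class-dependent speckle texture in a mid-peripheral band
(a bone-spicule pigment surrogate), a patient-specific intensity offset
shared by fellow eyes, and i.i.d. pixel noise.

The class signal is a speckle-density difference: X_LINKED images carry
``1 + effect_size`` times the base speckle density. At ``effect_size = 0``
the label is independent of the pixels by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .records import ImageRecord, ValidationError

# Geometry in fractions of image side, OS (left-eye) orientation.
# The optic disc sits nasally, i.e. on the right in an OS photo; OD images
# are the exact mirror, produced by flipping the rendered OS-oriented image.
DISC_COL_FRAC_OS = 0.72
DISC_ROW_FRAC = 0.50
DISC_RADIUS_FRAC = 0.09
MACULA_COL_FRAC_OS = 0.42
MACULA_RADIUS_FRAC = 0.14
SPECKLE_BAND_FRACS = (0.28, 0.46)  # annulus radii around image centre
BASE_SPECKLE_DENSITY = 0.010  # dots per band pixel, AUTOSOMAL class
SPECKLE_DEPTH = 0.25  # darkening per dot


@dataclass
class FixtureConfig:
    """Parameters of one synthetic cohort.

    ``effect_size`` multiplies the extra speckle density of the X_LINKED
    class; ``patient_effect_sd`` is the SD of a per-patient brightness
    offset shared by fellow eyes; ``class_balance`` is the fraction of
    patients assigned to class X_LINKED (rounded to an exact count).
    """

    n_patients: int = 40
    class_balance: float = 0.5
    prob_two_eyes: float = 0.95
    image_side: int = 64
    effect_size: float = 1.0
    patient_effect_sd: float = 0.05
    pixel_noise_sd: float = 0.02
    channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValidationError("class_balance must lie in [0, 1]")
        if not 0.0 <= self.prob_two_eyes <= 1.0:
            raise ValidationError("prob_two_eyes must lie in [0, 1]")
        if self.image_side < 16:
            raise ValidationError("image_side must be >= 16")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.patient_effect_sd < 0 or self.pixel_noise_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.channels not in (1, 3):
            raise ValidationError("channels must be 1 or 3")


def _gaussian_blob(side: int, row: float, col: float, radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    return np.exp(-d2 / (2.0 * radius**2))


def _draw_vessels(img: np.ndarray, rng: np.random.Generator) -> None:
    """Darken curvilinear arcs sweeping from the disc around the macula."""
    side = img.shape[0]
    disc = np.array([DISC_ROW_FRAC * side, DISC_COL_FRAC_OS * side])
    base_angle = np.pi  # pointing temporally (leftward in OS orientation)
    mask = np.zeros_like(img, dtype=bool)
    for sign in (+1.0, -1.0):
        for spread in (0.55, 1.05):
            theta = base_angle + sign * spread * (1.0 + 0.1 * rng.standard_normal())
            length = side * (0.55 + 0.1 * rng.random())
            bend = sign * side * 0.12 * (1.0 + 0.3 * rng.random())
            t = np.linspace(0.0, 1.0, 4 * side)
            direction = np.array([np.sin(theta), np.cos(theta)])
            normal = np.array([direction[1], -direction[0]])
            pts = (
                disc[None, :]
                + t[:, None] * length * direction[None, :]
                - np.sin(np.pi * t)[:, None] * bend * normal[None, :]
            )
            ij = np.round(pts).astype(int)
            ok = (ij[:, 0] >= 0) & (ij[:, 0] < side) & (ij[:, 1] >= 0) & (ij[:, 1] < side)
            mask[ij[ok, 0], ij[ok, 1]] = True
    img[mask] -= 0.18


def _stamp_speckles(
    img: np.ndarray, rng: np.random.Generator, density: float
) -> None:
    """Dark 2x2 dots at the given per-pixel density inside the mid-peripheral band."""
    side = img.shape[0]
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    centre = (side - 1) / 2.0
    radius = np.hypot(rr - centre, cc - centre)
    r_lo, r_hi = SPECKLE_BAND_FRACS[0] * side, SPECKLE_BAND_FRACS[1] * side
    band = np.flatnonzero(((radius >= r_lo) & (radius <= r_hi)).ravel())
    n_dots = rng.poisson(density * band.size)
    if n_dots == 0:
        return
    picks = rng.choice(band, size=min(n_dots, band.size), replace=False)
    rows, cols = np.unravel_index(picks, img.shape)
    for dr in (0, 1):
        for dc in (0, 1):
            r = np.clip(rows + dr, 0, side - 1)
            c = np.clip(cols + dc, 0, side - 1)
            img[r, c] -= SPECKLE_DEPTH


def speckle_band_mask(side: int) -> np.ndarray:
    """Boolean mask of the annulus where the class-dependent texture lives."""
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    centre = (side - 1) / 2.0
    radius = np.hypot(rr - centre, cc - centre)
    return (radius >= SPECKLE_BAND_FRACS[0] * side) & (radius <= SPECKLE_BAND_FRACS[1] * side)


def _render_eye(
    rng: np.random.Generator,
    side: int,
    eye: str,
    label: str,
    effect_size: float,
    patient_offset: float,
    pixel_noise_sd: float,
) -> np.ndarray:
    img = np.full((side, side), 0.45, dtype=np.float64)
    img += patient_offset
    img += 0.35 * _gaussian_blob(
        side, DISC_ROW_FRAC * side, DISC_COL_FRAC_OS * side, DISC_RADIUS_FRAC * side
    )
    img -= 0.15 * _gaussian_blob(
        side, DISC_ROW_FRAC * side, MACULA_COL_FRAC_OS * side, MACULA_RADIUS_FRAC * side
    )
    _draw_vessels(img, rng)
    density = BASE_SPECKLE_DENSITY * (1.0 + (effect_size if label == "X_LINKED" else 0.0))
    _stamp_speckles(img, rng, density)
    img += pixel_noise_sd * rng.standard_normal(img.shape)
    if eye == "OD":  # OD mirrors the OS geometry (pre-harmonization)
        img = img[:, ::-1]
    return np.clip(img, 0.0, 1.0)


def generate_fixture_dataset(config: FixtureConfig) -> list[ImageRecord]:
    """Generate a deterministic synthetic cohort from ``config``.

    Patients are assigned an exact class count ``round(class_balance *
    n_patients)`` for X_LINKED, shuffled; each patient contributes one or
    two eyes. Same config and seed yield byte-identical pixels.
    """
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F1C]))
    # independent Bernoulli labels per patient; redrawn (deterministically) in
    # the rare event a class ends up with fewer than two patients
    for _ in range(1000):
        draws = master.random(config.n_patients) < config.class_balance
        n1 = int(draws.sum())
        if (n1 >= min(2, config.n_patients) and config.n_patients - n1 >= 2) or (
            config.class_balance in (0.0, 1.0)
        ):
            break
    labels = np.where(draws, "X_LINKED", "AUTOSOMAL")
    records: list[ImageRecord] = []
    patient_streams = np.random.SeedSequence([config.seed, 0xA11]).spawn(config.n_patients)
    for p in range(config.n_patients):
        rng = np.random.default_rng(patient_streams[p])
        patient_id = f"P{p:03d}"
        label = str(labels[p])
        offset = config.patient_effect_sd * rng.standard_normal()
        two_eyes = rng.random() < config.prob_two_eyes
        eyes = ("OD", "OS") if two_eyes else (("OD",) if rng.random() < 0.5 else ("OS",))
        for eye in eyes:
            pixels = _render_eye(
                rng,
                config.image_side,
                eye,
                label,
                config.effect_size,
                offset,
                config.pixel_noise_sd,
            )
            if config.channels == 3:
                pixels = np.repeat(pixels[:, :, None], 3, axis=2)
            records.append(
                ImageRecord(
                    record_id=f"{patient_id}_{eye}",
                    patient_id=patient_id,
                    eye=eye,
                    label=label,
                    pixels=pixels,
                )
            )
    return records


def band_energy(pixels: np.ndarray) -> float:
    """High-pass energy of one image inside the speckle band.

    The statistic is the mean squared residual after a 3x3 local-mean
    filter, restricted to the mid-peripheral annulus; it responds to
    speckle density but not to smooth brightness offsets.
    """
    img = np.asarray(pixels, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    hp = img - ndimage.uniform_filter(img, size=3, mode="nearest")
    mask = speckle_band_mask(img.shape[0])
    return float(np.mean(hp[mask] ** 2))


def fixture_signal_check(
    records: list[ImageRecord], n_permutations: int, seed: int = 0
) -> float:
    """Permutation separation quantile of per-class speckle-band energy.

    Returns the fraction of label permutations whose absolute class-mean
    energy difference falls below the observed one (ties counted half).
    Values near 1 indicate a detectable class signal; under a true null the
    quantile is uniform.
    """
    if n_permutations <= 0:
        raise ValidationError("n_permutations must be positive")
    energies = np.array([band_energy(r.pixels) for r in records])
    is_pos = np.array([r.label == "X_LINKED" for r in records])
    if is_pos.sum() < 2 or (~is_pos).sum() < 2:
        raise ValidationError("need at least 2 records per class")
    obs = abs(energies[is_pos].mean() - energies[~is_pos].mean())
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(is_pos)
        perm_stats[i] = abs(energies[perm].mean() - energies[~perm].mean())
    less = np.sum(perm_stats < obs)
    ties = np.sum(perm_stats == obs)
    return float((less + 0.5 * ties) / n_permutations)
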