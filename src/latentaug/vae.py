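"""Latent codec: a small dense variational autoencoder trained from scratch.

The codec contract used by the expanders is minimal: an object exposing
``encode(pixels) -> LatentCode``, ``decode(z) -> pixels``, ``latent_dim``
and ``input_side``, with both directions deterministic. Any encoder-decoder
satisfying it (including pretrained image VAEs whose spatial latent grids
are flattened to a vector) can be plugged in; :class:`DenseVae` is the
reference implementation, sized to train on cohort-scale data in seconds.

Training minimizes mean pixel-wise squared reconstruction error plus
``kl_weight`` times the KL divergence of the Gaussian posterior from the
standard-normal prior, by Adam. Sampling (reparameterization) happens only
during training; ``encode`` returns the posterior mean and log-variance
and is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import ImageRecord, LatentCode, ValidationError

_LOGVAR_CLIP = 10.0


@dataclass
class VaeConfig:
    """Codec hyperparameters.

    ``output`` selects the decoder's final activation: ``linear`` (default;
    raw affine output, clipped to [0, 1] only when an image is emitted)
    optimizes the pixel-MSE objective far faster at cohort scale than
    ``sigmoid``, whose saturation slows texture learning.
    """

    latent_dim: int = 64
    kl_weight: float = 1e-3
    epochs: int = 80
    learning_rate: float = 1e-3
    hidden: int = 384
    batch_size: int = 16
    input_side: int = 64
    output: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValidationError("latent_dim must be >= 2")
        if self.kl_weight <= 0:
            raise ValidationError("kl_weight must be > 0")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValidationError("epochs >= 1 and learning_rate > 0 required")
        if self.output not in ("linear", "sigmoid"):
            raise ValidationError("output must be 'linear' or 'sigmoid'")


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        # scalar bias correction folded into the step size; in-place updates
        lr_t = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for k, g in grads.items():
            m, v = self.m[k], self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            denom = np.sqrt(v)
            denom += eps * np.sqrt(1.0 - b2**self.t)
            params[k] -= lr_t * m / denom


class DenseVae:
    """Fully connected VAE over flattened grayscale images."""

    def __init__(self, config: VaeConfig):
        self.config = config
        self.latent_dim = config.latent_dim
        self.input_side = config.input_side
        self.n_pixels = config.input_side**2
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xEA]))
        h, d, p = config.hidden, config.latent_dim, self.n_pixels

        def init(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params = {
            "W1": init((p, h), p),
            "b1": np.zeros(h, dtype=np.float32),
            "Wm": init((h, d), h),
            "bm": np.zeros(d, dtype=np.float32),
            "Wv": init((h, d), h),
            "bv": np.zeros(d, dtype=np.float32),
            "W2": init((d, h), d),
            "b2": np.zeros(h, dtype=np.float32),
            "W3": init((h, p), h),
            "b3": np.zeros(p, dtype=np.float32),
        }
        self.trace: list[dict] = []

    # -- forward pieces -------------------------------------------------
    def _encode_batch(self, x: np.ndarray):
        p = self.params
        h = _relu(x @ p["W1"] + p["b1"])
        mu = h @ p["Wm"] + p["bm"]
        lv = np.clip(h @ p["Wv"] + p["bv"], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return h, mu, lv

    def _decode_batch(self, z: np.ndarray):
        p = self.params
        h2 = _relu(z @ p["W2"] + p["b2"])
        pre = h2 @ p["W3"] + p["b3"]
        return h2, (_sigmoid(pre) if self.config.output == "sigmoid" else pre)

    # -- public codec contract ------------------------------------------
    def encode(self, pixels: np.ndarray, record_id: str = "") -> LatentCode:
        x = self._flatten(pixels)
        _, mu, lv = self._encode_batch(x[None, :])
        return LatentCode(mean=mu[0], log_var=lv[0], source_record_id=record_id)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64).ravel()
        if z.size != self.latent_dim:
            raise ValidationError(
                f"latent vector length {z.size} != latent_dim {self.latent_dim}"
            )
        _, xhat = self._decode_batch(z[None, :])
        img = xhat[0].reshape(self.input_side, self.input_side)
        return np.clip(img, 0.0, 1.0).astype(np.float32)

    def _flatten(self, pixels: np.ndarray) -> np.ndarray:
        arr = np.asarray(pixels, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        if arr.shape != (self.input_side, self.input_side):
            raise ValidationError(
                f"image shape {arr.shape} does not match codec input_side "
                f"{self.input_side}"
            )
        return arr.ravel()

    # -- training --------------------------------------------------------
    def fit(self, records: Sequence[ImageRecord]) -> list[dict]:
        cfg = self.config
        if len(records) < 8:
            raise ValidationError("VAE training needs at least 8 images")
        shapes = {r.pixels.shape[:2] for r in records}
        if len(shapes) != 1:
            raise ValidationError(f"inconsistent image shapes: {sorted(shapes)}")
        X = np.stack([self._flatten(r.pixels) for r in records]).astype(np.float32)
        n = X.shape[0]
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A1]))
        opt = _Adam(self.params, cfg.learning_rate)
        beta = cfg.kl_weight
        p = self.params
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            ep_recon = ep_kl = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                x = X[idx]
                B = x.shape[0]
                h, mu, lv = self._encode_batch(x)
                eps = rng.standard_normal(mu.shape).astype(np.float32)
                z = mu + np.exp(0.5 * lv) * eps
                h2, xhat = self._decode_batch(z)

                recon = float(np.mean((xhat - x) ** 2))
                kl = float(np.mean(0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv, axis=1)))
                if not np.isfinite(recon) or not np.isfinite(kl):
                    raise RuntimeError(
                        f"non-finite VAE loss at epoch {epoch}: recon={recon}, kl={kl}"
                    )
                ep_recon += recon * B
                ep_kl += kl * B

                # backward
                d_xhat = 2.0 * (xhat - x) / (B * x.shape[1])
                if cfg.output == "sigmoid":
                    d_logits3 = d_xhat * xhat * (1.0 - xhat)
                else:
                    d_logits3 = d_xhat
                gW3 = h2.T @ d_logits3
                gb3 = d_logits3.sum(0)
                d_h2 = (d_logits3 @ p["W3"].T) * (h2 > 0)
                gW2 = z.T @ d_h2
                gb2 = d_h2.sum(0)
                d_z = d_h2 @ p["W2"].T
                # KL grads (mean over batch of 0.5*sum(exp(lv)+mu^2-1-lv))
                d_mu = d_z + beta * mu / B
                d_lv = d_z * 0.5 * np.exp(0.5 * lv) * eps + beta * 0.5 * (np.exp(lv) - 1.0) / B
                gWm = h.T @ d_mu
                gbm = d_mu.sum(0)
                gWv = h.T @ d_lv
                gbv = d_lv.sum(0)
                d_h = (d_mu @ p["Wm"].T + d_lv @ p["Wv"].T) * (h > 0)
                gW1 = x.T @ d_h
                gb1 = d_h.sum(0)
                opt.step(
                    p,
                    {
                        "W1": gW1, "b1": gb1, "Wm": gWm, "bm": gbm,
                        "Wv": gWv, "bv": gbv, "W2": gW2, "b2": gb2,
                        "W3": gW3, "b3": gb3,
                    },
                )
            entry = {
                "epoch": epoch,
                "recon_loss": ep_recon / n,
                "kl_loss": ep_kl / n,
                "total": ep_recon / n + beta * ep_kl / n,
            }
            self.trace.append(entry)
        return self.trace

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, __config__=json.dumps(asdict(self.config)), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "DenseVae":
        with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path,
                     allow_pickle=False) as data:
            cfg = VaeConfig(**json.loads(str(data["__config__"])))
            vae = cls(cfg)
            for k in vae.params:
                vae.params[k] = data[k]
        return vae


def train_vae(records: Sequence[ImageRecord], config: VaeConfig) -> tuple[DenseVae, list[dict]]:
    """Train a DenseVae on the given records; returns (codec, loss trace)."""
    vae = DenseVae(config)
    trace = vae.fit(records)
    return vae, trace


def trace_to_csv(trace: list[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("epoch,recon_loss,kl_loss,total\n")
        for row in trace:
            fh.write(f"{row['epoch']},{row['recon_loss']},{row['kl_loss']},{row['total']}\n")


class DownsampleCodec:
    """Trivial lossless-in-spirit codec: block-mean downsample as 'latent'.

    Satisfies the codec contract without any training: ``encode`` averages
    the image over a grid of blocks and flattens it; ``decode`` paints each
    block back at its mean. Used to exercise expansion logic independently
    of VAE quality, and as the contract-conformance reference in tests.
    """

    def __init__(self, input_side: int, grid: int = 8):
        if input_side % grid:
            raise ValidationError("input_side must be divisible by grid")
        self.input_side = input_side
        self.grid = grid
        self.latent_dim = grid * grid

    def encode(self, pixels: np.ndarray, record_id: str = "") -> LatentCode:
        arr = np.asarray(pixels, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        if arr.shape != (self.input_side, self.input_side):
            raise ValidationError("image shape does not match codec input_side")
        b = self.input_side // self.grid
        z = arr.reshape(self.grid, b, self.grid, b).mean(axis=(1, 3)).ravel()
        return LatentCode(mean=z, log_var=np.zeros_like(z), source_record_id=record_id)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64).ravel()
        if z.size != self.latent_dim:
            raise ValidationError("wrong latent length")
        b = self.input_side // self.grid
        img = np.kron(z.reshape(self.grid, self.grid), np.ones((b, b)))
        return np.clip(img, 0.0, 1.0).astype(np.float32)
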