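"""Convolutional variational autoencoder for OCT B-scans.

One VAE is trained per eye on [0, 1] B-scan images. The encoder is a stack
of stride-2 convolutions with ReLU activations ending in a dense layer that
emits the latent posterior mean and log-variance; the decoder mirrors it
with transposed convolutions and LeakyReLU activations and a sigmoid output.
Training minimises

    L = L_MSE + beta * L_KL

where L_MSE is the mean squared pixel reconstruction error, L_KL the
standard (nonnegative) Gaussian KL divergence to the unit prior summed over
latent dimensions, and beta is linearly annealed from ``beta_start`` to
``beta_max`` over the first ``anneal_epochs`` epochs, then held constant.
Inference is deterministic: downstream stages always use the posterior mean.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from octcvd.errors import ConfigurationError
from octcvd import nn
from octcvd.phantom import OCTVolume


@dataclass(frozen=True)
class VaeConfig:
    latent_dim: int = 128
    conv_layers: int = 6
    base_channels: int = 8
    max_channels: int = 64
    image_size: int = 128
    epochs: int = 100
    beta_start: float = 0.001
    beta_max: float = 0.01
    anneal_epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    leaky_alpha: float = 0.2
    #: initial log-variance head bias. Starting near-deterministic
    #: (sigma ~ e^-2) lets reconstruction gradients reach the posterior
    #: means before sampling noise swamps them; with a unit-variance start
    #: the sampled latents carry no signal and the decoder learns to
    #: ignore them (posterior collapse).
    logvar_init: float = -4.0
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if not 0 < self.beta_start <= self.beta_max:
            raise ConfigurationError("need 0 < beta_start <= beta_max")
        if self.anneal_epochs > self.epochs:
            raise ConfigurationError("anneal_epochs must be <= epochs")
        if self.image_size % (2**self.conv_layers) != 0:
            raise ConfigurationError(
                "image_size must be divisible by 2**conv_layers"
            )

    @property
    def channels(self) -> List[int]:
        return [
            min(self.base_channels * 2**i, self.max_channels)
            for i in range(self.conv_layers)
        ]


@dataclass
class LatentCode:
    """Gaussian posterior parameters for one image (or a batch)."""

    mean: np.ndarray
    logvar: np.ndarray

    @property
    def D(self) -> int:
        return self.mean.shape[-1]


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    mse: float
    kl: float
    beta: float


def kl_anneal_weight(epoch: int, config: VaeConfig) -> float:
    """Linear KL-weight ramp: beta_start at epoch 0, beta_max from
    ``anneal_epochs`` onward."""
    if epoch < 0:
        raise ConfigurationError("epoch must be >= 0")
    frac = min(epoch / config.anneal_epochs, 1.0) if config.anneal_epochs else 1.0
    return config.beta_start + (config.beta_max - config.beta_start) * frac


def gaussian_kl(mean: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(mean, exp(logvar)) || N(0, I) ), summed over latent dims and
    averaged over the batch if batched. Nonnegative; zero iff the posterior
    equals the prior."""
    mean = np.atleast_2d(mean)
    logvar = np.atleast_2d(logvar)
    per_item = 0.5 * np.sum(np.exp(logvar) + mean**2 - 1.0 - logvar, axis=1)
    return float(per_item.mean())


def vae_loss(
    x: np.ndarray, xhat: np.ndarray, code: LatentCode, beta: float
) -> LossBreakdown:
    """Composite loss on one image pair (or batch) and its latent code."""
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ConfigurationError(
            f"shape mismatch: x {x.shape} vs reconstruction {xhat.shape}"
        )
    mse = float(np.mean((x - xhat) ** 2))
    kl = gaussian_kl(code.mean, code.logvar)
    return LossBreakdown(total=mse + beta * kl, mse=mse, kl=kl, beta=beta)


class ConvVAE:
    """Encoder/decoder pair with manual backprop (see :mod:`octcvd.nn`)."""

    def __init__(self, config: VaeConfig):
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        D = config.latent_dim
        hs = config.image_size // 2**config.conv_layers
        self._hs, self._clast = hs, ch[-1]
        flat = ch[-1] * hs * hs

        enc: List[nn.Layer] = []
        cin = 1
        for c in ch:
            enc.append(nn.Conv2d(cin, c, rng=rng, dtype=dtype))
            enc.append(nn.ReLU())
            cin = c
        enc.append(nn.Flatten())
        head = nn.Dense(flat, 2 * D, rng=rng, dtype=dtype)
        head.b[D:] = config.logvar_init
        enc.append(head)
        self.encoder = nn.Sequential(enc)

        dec: List[nn.Layer] = [
            nn.Dense(D, flat, rng=rng, dtype=dtype),
            nn.LeakyReLU(config.leaky_alpha),
            nn.Reshape((ch[-1], hs, hs)),
        ]
        for cout, c in zip(reversed([1] + ch[:-1]), reversed(ch)):
            dec.append(nn.ConvTranspose2d(c, cout, rng=rng, dtype=dtype))
            if cout != 1:
                dec.append(nn.LeakyReLU(config.leaky_alpha))
        dec.append(nn.Sigmoid())
        self.decoder = nn.Sequential(dec)

    # ------------------------------ inference ------------------------------

    def _as_batch(self, x: np.ndarray) -> Tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=self.config.dtype)
        single = x.ndim == 2
        if single:
            x = x[None]
        s = self.config.image_size
        if x.shape[-2:] != (s, s):
            raise ConfigurationError(
                f"expected {s}x{s} images, got {x.shape[-2:]}"
            )
        return x[:, None, :, :], single

    def encode(self, image: np.ndarray) -> LatentCode:
        xb, single = self._as_batch(image)
        h = self.encoder.forward(xb)
        D = self.config.latent_dim
        mean, logvar = h[:, :D], np.clip(h[:, D:], -15.0, 15.0)
        if single:
            mean, logvar = mean[0], logvar[0]
        return LatentCode(mean=mean, logvar=logvar)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=self.config.dtype)
        single = z.ndim == 1
        if single:
            z = z[None]
        if z.shape[1] != self.config.latent_dim:
            raise ConfigurationError(
                f"latent must have length {self.config.latent_dim}"
            )
        y = self.decoder.forward(z)[:, 0]
        return y[0] if single else y

    def reconstruct(self, image: np.ndarray) -> np.ndarray:
        """Deterministic reconstruction through the posterior mean."""
        return self.decode(self.encode(image).mean)

    # ------------------------------ training -------------------------------

    def _train_step(self, x: np.ndarray, beta: float, opt: nn.Adam,
                    rng: np.random.Generator) -> LossBreakdown:
        xb = x[:, None, :, :]
        B = xb.shape[0]
        P = xb.shape[-1] * xb.shape[-2]
        D = self.config.latent_dim

        h = self.encoder.forward(xb)
        mu, logvar = h[:, :D], np.clip(h[:, D:], -15.0, 15.0)
        std = np.exp(0.5 * logvar)
        eps = rng.standard_normal(mu.shape).astype(mu.dtype)
        z = mu + std * eps
        xhat = self.decoder.forward(z)

        diff = xhat - xb
        mse = float(np.mean(diff.astype(np.float64) ** 2))
        kl = gaussian_kl(mu, logvar)

        self.encoder.zero_grad()
        self.decoder.zero_grad()
        dxhat = (2.0 / (B * P)) * diff
        dz = self.decoder.backward(dxhat)
        dmu = dz + beta * mu / B
        dlogvar = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(logvar) - 1.0) / B
        dh = np.concatenate([dmu, dlogvar], axis=1).astype(h.dtype)
        self.encoder.backward(dh)
        opt.step()
        return LossBreakdown(total=mse + beta * kl, mse=mse, kl=kl, beta=beta)

    def eval_loss(self, images: np.ndarray, beta: float) -> LossBreakdown:
        """Deterministic loss (posterior mean, no sampling) over a set."""
        code = self.encode(images)
        xhat = self.decode(code.mean)
        return vae_loss(images, xhat, code, beta)

    # ---------------------------- persistence ------------------------------

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p in self.encoder.params + self.decoder.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.encoder.params + self.decoder.params
        if len(weights) != len(params):
            raise ConfigurationError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ConfigurationError("weight shapes do not match architecture")
            p[...] = w

    def save(self, path) -> None:
        np.savez(path, *self.get_weights())
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as f:
            json.dump({"config": asdict(self.config)}, f, indent=2)

    @classmethod
    def load(cls, path) -> "ConvVAE":
        with open(str(path) + ".json") as f:
            cfg = VaeConfig(**json.load(f)["config"])
        model = cls(cfg)
        with np.load(str(path) if str(path).endswith(".npz") else str(path)) as data:
            model.set_weights([data[k] for k in data.files])
        return model


def split_622(
    n: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded 6:2:2 train/validation/test index split."""
    perm = rng.permutation(n)
    n_train = int(round(0.6 * n))
    n_val = int(round(0.2 * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def train_vae(
    images: np.ndarray,
    config: VaeConfig,
    init_weights: Optional[Sequence[np.ndarray]] = None,
) -> Tuple[ConvVAE, pd.DataFrame]:
    """Train a VAE on a stack of images with a 6:2:2 internal split.

    Returns the model and a per-epoch loss log (train MSE/KL/total at the
    annealed beta, plus deterministic validation loss). ``init_weights``
    warm-starts from a previously trained model of identical architecture.
    """
    images = np.asarray(images, dtype=config.dtype)
    rng = np.random.default_rng(config.seed)
    i_train, i_val, _ = split_622(len(images), rng)
    if len(i_train) == 0:
        raise ConfigurationError("empty training set")
    x_train, x_val = images[i_train], images[i_val]

    model = ConvVAE(config)
    if init_weights is not None:
        model.set_weights(init_weights)
    opt = nn.Adam(
        model.encoder.params + model.decoder.params,
        model.encoder.grads + model.decoder.grads,
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )

    log = []
    for epoch in range(config.epochs):
        beta = kl_anneal_weight(epoch, config)
        order = rng.permutation(len(x_train))
        tot = np.zeros(3)
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = x_train[order[start : start + config.batch_size]]
            lb = model._train_step(batch, beta, opt, rng)
            tot += (lb.total, lb.mse, lb.kl)
            n_batches += 1
        tr = tot / n_batches
        val = model.eval_loss(x_val, beta) if len(x_val) else None
        log.append(
            {
                "epoch": epoch,
                "beta": beta,
                "train_total": tr[0],
                "train_mse": tr[1],
                "train_kl": tr[2],
                "val_total": val.total if val else np.nan,
                "val_mse": val.mse if val else np.nan,
                "val_kl": val.kl if val else np.nan,
            }
        )
    return model, pd.DataFrame(log)


def central_slice_index(n_bscans: int) -> int:
    """0-based index of the central B-scan (the 64th of 128)."""
    return (n_bscans - 1) // 2


def extract_eye_latent(
    volume: Union[OCTVolume, np.ndarray],
    model: ConvVAE,
    mode: Union[str, Sequence[int]] = "all",
) -> np.ndarray:
    """Per-eye latent vector: mean of per-B-scan posterior means.

    ``mode`` is ``"all"`` (every B-scan; the default, so the whole volume
    informs the representation), ``"central_slice"``, or an explicit list
    of slice indices.
    """
    bscans = volume.bscans if isinstance(volume, OCTVolume) else np.asarray(volume)
    if isinstance(mode, str):
        if mode == "all":
            idx = np.arange(bscans.shape[0])
        elif mode == "central_slice":
            idx = np.array([central_slice_index(bscans.shape[0])])
        else:
            raise ConfigurationError(f"unknown latent aggregation mode {mode!r}")
    else:
        idx = np.asarray(list(mode), dtype=int)
    code = model.encode(bscans[idx])
    means = np.atleast_2d(code.mean)
    return means.mean(axis=0)
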