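"""Per-client variational autoencoders and latent signatures.

Each client trains a small VAE on its private data and shares only a compact
*latent signature* with the server: a normalized histogram of its latent
posterior means (all latent dimensions pooled into one 1-D distribution) plus
the scalar population variance of those pooled coordinates, together with the
sample count and the number of distinct label classes.  The histogram feeds
the Jensen-Shannon grouping; the variance feeds the aggregation weighting.

The VAE objective is the negative evidence lower bound: a reconstruction
negative log-likelihood (Gaussian with unit variance for real-valued
features, i.e. squared error, or Bernoulli for inputs in [0, 1]) plus the
closed-form KL divergence from the diagonal-Gaussian posterior to a standard
normal prior.  Sampling uses the reparameterization trick with seeded noise,
so training is fully deterministic given the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .fl_core import ClientDataset, ConfigurationError

__all__ = [
    "VAEConfig",
    "LatentSignature",
    "VAEModel",
    "TrainingDivergenceError",
    "train_vae",
    "encode_dataset",
    "summarize_signature",
    "gaussian_kl",
    "client_signature",
]

_HIST_SMOOTHING = 1e-10


class TrainingDivergenceError(RuntimeError):
    """Raised when the VAE loss becomes non-finite during training."""


@dataclass(frozen=True)
class VAEConfig:
    latent_dim: int = 8
    encoder_widths: tuple[int, ...] = (16,)
    epochs: int = 5
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0
    init_seed: int | None = None  # shared across clients when set by the server
    grad_clip: float = 5.0  # global gradient-norm ceiling; <=0 disables
    histogram_bins: int = 20
    histogram_range: tuple[float, float] = (-4.0, 4.0)
    likelihood: str = "gaussian"

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ConfigurationError("latent_dim must be >= 1")
        if self.histogram_bins < 2:
            raise ConfigurationError("histogram_bins must be >= 2")
        lo, hi = self.histogram_range
        if not lo < hi:
            raise ConfigurationError("histogram_range must satisfy lower < upper")
        if self.likelihood not in ("gaussian", "bernoulli"):
            raise ConfigurationError(f"unknown likelihood {self.likelihood!r}")
        if self.epochs < 1 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ConfigurationError("epochs, learning_rate, batch_size must be positive")
        object.__setattr__(self, "encoder_widths", tuple(int(w) for w in self.encoder_widths))


@dataclass
class LatentSignature:
    """The only client-to-server artifact before federated training starts."""

    histogram: np.ndarray
    variance: float
    sample_count: int
    label_class_count: int
    client_id: str | int = 0

    def __post_init__(self):
        self.histogram = np.asarray(self.histogram, dtype=np.float64)
        if np.any(self.histogram < 0):
            raise ValueError("histogram entries must be non-negative")
        if abs(self.histogram.sum() - 1.0) > 1e-9:
            raise ValueError("histogram must sum to 1")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.sample_count < 1 or self.label_class_count < 1:
            raise ValueError("sample_count and label_class_count must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "client_id": self.client_id,
                "histogram": self.histogram.tolist(),
                "variance": float(self.variance),
                "n": self.sample_count,
                "l": self.label_class_count,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LatentSignature":
        d = json.loads(text)
        return cls(
            histogram=np.asarray(d["histogram"]),
            variance=d["variance"],
            sample_count=d["n"],
            label_class_count=d["l"],
            client_id=d["client_id"],
        )


@dataclass
class VAEModel:
    """Trained encoder/decoder parameters plus the architecture metadata."""

    params: dict[str, np.ndarray]
    input_dim: int
    latent_dim: int
    encoder_widths: tuple[int, ...]
    likelihood: str

    def copy(self) -> "VAEModel":
        return VAEModel(
            {k: v.copy() for k, v in self.params.items()},
            self.input_dim, self.latent_dim, self.encoder_widths, self.likelihood,
        )


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Mean (over rows) KL from N(mu, diag exp(logvar)) to the standard normal."""
    per_sample = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)
    return float(per_sample.mean())


# ---------------------------------------------------------------------------
# network construction and passes
# ---------------------------------------------------------------------------


def _init_vae(input_dim: int, cfg: VAEConfig, rng: np.random.Generator) -> VAEModel:
    params: dict[str, np.ndarray] = {}
    widths = (input_dim,) + cfg.encoder_widths
    for i in range(len(widths) - 1):
        params[f"enc{i}.W"] = nn.glorot_uniform(rng, (widths[i], widths[i + 1]))
        params[f"enc{i}.b"] = np.zeros(widths[i + 1])
    params["mu.W"] = nn.glorot_uniform(rng, (widths[-1], cfg.latent_dim))
    params["mu.b"] = np.zeros(cfg.latent_dim)
    params["logvar.W"] = nn.glorot_uniform(rng, (widths[-1], cfg.latent_dim))
    params["logvar.b"] = np.zeros(cfg.latent_dim)
    dwidths = (cfg.latent_dim,) + tuple(reversed(cfg.encoder_widths))
    for i in range(len(dwidths) - 1):
        params[f"dec{i}.W"] = nn.glorot_uniform(rng, (dwidths[i], dwidths[i + 1]))
        params[f"dec{i}.b"] = np.zeros(dwidths[i + 1])
    params["out.W"] = nn.glorot_uniform(rng, (dwidths[-1], input_dim))
    params["out.b"] = np.zeros(input_dim)
    return VAEModel(params, input_dim, cfg.latent_dim, cfg.encoder_widths, cfg.likelihood)


def _encode(model: VAEModel, x: np.ndarray):
    caches = []
    a = x
    for i in range(len(model.encoder_widths)):
        a, c1 = nn.dense_forward(a, model.params[f"enc{i}.W"], model.params[f"enc{i}.b"])
        a, c2 = nn.relu_forward(a)
        caches.append((i, c1, c2))
    mu, cmu = nn.dense_forward(a, model.params["mu.W"], model.params["mu.b"])
    logvar, clv = nn.dense_forward(a, model.params["logvar.W"], model.params["logvar.b"])
    return mu, logvar, (caches, cmu, clv)


def _decode(model: VAEModel, z: np.ndarray):
    caches = []
    a = z
    for i in range(len(model.encoder_widths)):
        a, c1 = nn.dense_forward(a, model.params[f"dec{i}.W"], model.params[f"dec{i}.b"])
        a, c2 = nn.relu_forward(a)
        caches.append((i, c1, c2))
    out, cout = nn.dense_forward(a, model.params["out.W"], model.params["out.b"])
    return out, (caches, cout)


def _vae_batch(model: VAEModel, x: np.ndarray, eps: np.ndarray):
    """Loss terms and parameter gradients for one mini-batch.

    Returns (recon, kl, grads) where recon and kl are per-sample means, so
    recon + kl is the (negative ELBO) training objective for the batch.
    """
    n = x.shape[0]
    mu, logvar, enc_cache = _encode(model, x)
    logvar = np.clip(logvar, -10.0, 10.0)
    std = np.exp(0.5 * logvar)
    z = mu + std * eps
    raw, dec_cache = _decode(model, z)

    grads = {k: None for k in model.params}
    if model.likelihood == "gaussian":
        diff = raw - x
        recon = 0.5 * float(np.sum(diff**2)) / n
        draw = diff / n
    else:  # bernoulli with logits
        p = nn.sigmoid(raw)
        recon = float(
            np.sum(np.logaddexp(0.0, raw) - x * raw)
        ) / n
        draw = (p - x) / n
    kl = gaussian_kl(mu, logvar)

    # decoder backward
    dec_caches, cout = dec_cache
    da, dw, db = nn.dense_backward(draw, cout)
    grads["out.W"], grads["out.b"] = dw, db
    for i, c1, c2 in reversed(dec_caches):
        da = nn.relu_backward(da, c2)
        da, dw, db = nn.dense_backward(da, c1)
        grads[f"dec{i}.W"], grads[f"dec{i}.b"] = dw, db
    dz = da

    # through the reparameterization and the KL term
    dmu = dz + mu / n
    dlogvar = dz * eps * 0.5 * std - 0.5 * (1.0 - np.exp(logvar)) / n

    enc_caches, cmu, clv = enc_cache
    da_mu, dw, db = nn.dense_backward(dmu, cmu)
    grads["mu.W"], grads["mu.b"] = dw, db
    da_lv, dw, db = nn.dense_backward(dlogvar, clv)
    grads["logvar.W"], grads["logvar.b"] = dw, db
    da = da_mu + da_lv
    for i, c1, c2 in reversed(enc_caches):
        da = nn.relu_backward(da, c2)
        da, dw, db = nn.dense_backward(da, c1)
        grads[f"enc{i}.W"], grads[f"enc{i}.b"] = dw, db
    return recon, kl, grads


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def train_vae(data: ClientDataset, cfg: VAEConfig) -> tuple[VAEModel, float, list[dict]]:
    """Train a client VAE by seeded mini-batch SGD on the negative ELBO.

    Returns the trained model, the final epoch's mean per-sample loss, and a
    per-epoch history of ``{"recon", "kl", "total"}`` terms (each the mean
    over that epoch's batches).  ``cfg.init_seed``, when set, controls the
    weight initialization separately from the training noise, so a server can
    broadcast one common starting point to all clients.
    """
    x = data.features.reshape(data.n_samples, -1)
    input_dim = x.shape[1]
    init_rng = np.random.default_rng(cfg.init_seed if cfg.init_seed is not None else cfg.seed)
    model = _init_vae(input_dim, cfg, init_rng)
    rng = np.random.default_rng(cfg.seed)

    history: list[dict] = []
    final_loss = np.nan
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        recon_sum = kl_sum = 0.0
        weight = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x[idx]
            eps = rng.standard_normal((xb.shape[0], cfg.latent_dim))
            recon, kl, grads = _vae_batch(model, xb, eps)
            if not np.isfinite(recon + kl):
                raise TrainingDivergenceError(
                    f"non-finite VAE loss at epoch {epoch} (recon={recon}, kl={kl})"
                )
            scale = 1.0
            if cfg.grad_clip > 0:
                norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
                scale = min(1.0, cfg.grad_clip / max(norm, 1e-12))
            for k, g in grads.items():
                model.params[k] -= cfg.learning_rate * scale * g
            recon_sum += recon * xb.shape[0]
            kl_sum += kl * xb.shape[0]
            weight += xb.shape[0]
        epoch_recon, epoch_kl = recon_sum / weight, kl_sum / weight
        history.append({"recon": epoch_recon, "kl": epoch_kl,
                        "total": epoch_recon + epoch_kl})
        final_loss = epoch_recon + epoch_kl
    return model, float(final_loss), history


def encode_dataset(model: VAEModel, data: ClientDataset) -> np.ndarray:
    """Posterior means for every sample (no sampling noise); (n, latent_dim)."""
    x = data.features.reshape(data.n_samples, -1)
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match encoder input {model.input_dim}"
        )
    mu, _, _ = _encode(model, x)
    return mu


def summarize_signature(latents: np.ndarray, data: ClientDataset,
                        cfg: VAEConfig) -> LatentSignature:
    """Distill a latent matrix into the client's shareable signature.

    Each latent dimension is binned separately with ``cfg.histogram_bins``
    equal-width bins over ``cfg.histogram_range`` (out-of-range values
    clipped into the end bins) and the per-dimension histograms are
    concatenated into one probability vector of length
    ``latent_dim * histogram_bins``, then smoothed by adding 1e-10 per bin
    and renormalized.  Concatenation keeps the signature linear in the
    latent dimension while remaining sensitive to shifts in any single
    dimension, which a pooled 1-D histogram would dilute.  The variance is
    the population variance of all latent coordinates pooled.
    """
    latents = np.asarray(latents, dtype=np.float64)
    if latents.size == 0:
        raise ValueError("latents must be non-empty")
    if latents.ndim == 1:
        latents = latents[:, None]
    lo, hi = cfg.histogram_range
    if not lo < hi:
        raise ConfigurationError("histogram_range must have positive width")
    per_dim = [
        np.histogram(np.clip(latents[:, d], lo, hi),
                     bins=cfg.histogram_bins, range=(lo, hi))[0]
        for d in range(latents.shape[1])
    ]
    counts = np.concatenate(per_dim).astype(np.float64)
    hist = counts / counts.sum()
    hist = hist + _HIST_SMOOTHING
    hist /= hist.sum()
    pooled = latents.ravel()
    return LatentSignature(
        histogram=hist,
        variance=float(pooled.var()),
        sample_count=data.n_samples,
        label_class_count=data.label_class_count,
        client_id=data.client_id,
    )


def client_signature(data: ClientDataset, cfg: VAEConfig) -> LatentSignature:
    """Convenience pipeline: train the client VAE, encode, summarize."""
    model, _, _ = train_vae(data, cfg)
    return summarize_signature(encode_dataset(model, data), data, cfg)


def write_signatures(signatures: Sequence[LatentSignature], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sig in signatures:
        (directory / f"signature_{sig.client_id}.json").write_text(sig.to_json())
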