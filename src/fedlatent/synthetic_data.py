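"""Seeded synthetic federations with planted ground-truth groups.

Emulates the heterogeneity a federated network of medical centers exhibits:
clients differ in sample volume (quantity skew), label mix (Dirichlet label
skew), and feature distribution (each planted group shifts its Gaussian
class blobs by a controllable number of within-blob standard deviations).
Group identity expresses both the feature shift and the label skew, so
groups are learnable from features alone — signatures never see labels.

Two generators share one manifest contract: ``generate_federation`` yields
tabular Gaussian-blob data; ``generate_image_federation`` renders small
grayscale images with class-dependent geometric patterns and group-dependent
contrast/noise, a desk-scale stand-in for imaging data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .fl_core import ClientDataset, ConfigurationError

__all__ = [
    "SyntheticSpec",
    "FederationManifest",
    "generate_federation",
    "generate_image_federation",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the federation generator.

    ``label_skew`` is the Dirichlet concentration from which each group's
    label distribution is drawn (smaller = more skewed); it may be a scalar
    or one value per group.  ``feature_separation`` is the distance between group blob
    centers in units of the within-blob standard deviation (which is 1)."""

    num_clients: int = 12
    num_groups: int = 3
    num_classes: int = 3
    feature_dim: int = 8  # image side in image mode
    samples_per_client: tuple[int, int] = (80, 120)
    label_skew: float | tuple[float, ...] = 1.0
    feature_separation: float = 4.0
    class_separation: float = 3.0
    image_noise: float = 0.1
    test_size: int = 500
    seed: int = 0

    def __post_init__(self):
        if not self.num_clients >= self.num_groups >= 1:
            raise ConfigurationError("need num_clients >= num_groups >= 1")
        if self.num_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.feature_separation < 0:
            raise ConfigurationError("feature_separation must be >= 0")
        lo, hi = self.samples_per_client
        if not 1 <= lo <= hi:
            raise ConfigurationError("samples_per_client must be a valid range")

    def skew_for_group(self, g: int) -> float:
        if np.isscalar(self.label_skew):
            return float(self.label_skew)
        return float(self.label_skew[g])


@dataclass
class FederationManifest:
    clients: list[ClientDataset]
    group_ids: list[int]  # planted ground-truth group per client
    test_set: ClientDataset
    spec: SyntheticSpec

    def __post_init__(self):
        if len(self.clients) != len(self.group_ids):
            raise ValueError("one group id per client required")
        if any(g < 0 or g >= self.spec.num_groups for g in self.group_ids):
            raise ValueError("ground-truth group id out of range")

    @property
    def num_clients(self) -> int:
        return len(self.clients)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for ds in self.clients:
            np.savez(directory / f"client_{ds.client_id}.npz",
                     features=ds.features, labels=ds.labels)
        np.savez(directory / "test_set.npz",
                 features=self.test_set.features, labels=self.test_set.labels)
        manifest = {
            "client_ids": [ds.client_id for ds in self.clients],
            "group_ids": self.group_ids,
            "seed": self.spec.seed,
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(self.spec).items()},
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "FederationManifest":
        directory = Path(directory)
        meta = json.loads((directory / "manifest.json").read_text())
        spec_kwargs = dict(meta["spec"])
        for key in ("samples_per_client", "label_skew"):
            if isinstance(spec_kwargs.get(key), list):
                spec_kwargs[key] = tuple(spec_kwargs[key])
        spec = SyntheticSpec(**spec_kwargs)
        clients = []
        for cid in meta["client_ids"]:
            with np.load(directory / f"client_{cid}.npz") as a:
                clients.append(ClientDataset(a["features"], a["labels"], client_id=cid))
        with np.load(directory / "test_set.npz") as a:
            test = ClientDataset(a["features"], a["labels"], client_id="test")
        return cls(clients, list(meta["group_ids"]), test, spec)


def _group_label_mixes(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    """One label distribution per group, drawn from the group's Dirichlet.

    Clients inherit their group's mix (their empirical label proportions
    still differ by multinomial sampling), so group identity carries the
    label skew alongside the feature shift."""
    return np.stack([
        rng.dirichlet(np.full(spec.num_classes, spec.skew_for_group(g)))
        for g in range(spec.num_groups)
    ])


def _group_offsets(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    """Group blob offsets: near-orthogonal directions scaled to the requested
    separation (within-blob std is 1, so units coincide)."""
    d, g = spec.feature_dim, spec.num_groups
    raw = rng.standard_normal((d, g))
    if d >= g:
        q, _ = np.linalg.qr(raw)
        dirs = q[:, :g].T
    else:
        dirs = raw.T / np.linalg.norm(raw.T, axis=1, keepdims=True)
    return spec.feature_separation * dirs


def generate_federation(spec: SyntheticSpec) -> FederationManifest:
    """Tabular federation: class-conditional unit-variance Gaussian blobs,
    shifted per group, with Dirichlet label skew and quantity skew.

    Clients are assigned to groups round-robin (client k -> group k mod G).
    The held-out test set is drawn from the pooled mixture of all groups
    with uniform labels, disjoint from every client's training samples by
    construction (fresh draws)."""
    rng = np.random.default_rng(spec.seed)
    centers = spec.class_separation * rng.standard_normal(
        (spec.num_classes, spec.feature_dim))
    offsets = _group_offsets(rng, spec)
    mixes = _group_label_mixes(rng, spec)

    lo, hi = spec.samples_per_client
    clients, group_ids = [], []
    for k in range(spec.num_clients):
        g = k % spec.num_groups
        n = int(rng.integers(lo, hi + 1))
        labels = rng.choice(spec.num_classes, size=n, p=mixes[g])
        x = centers[labels] + offsets[g] + rng.standard_normal((n, spec.feature_dim))
        clients.append(ClientDataset(x, labels, client_id=k))
        group_ids.append(g)

    test_labels = rng.choice(spec.num_classes, size=spec.test_size)
    test_groups = rng.integers(0, spec.num_groups, size=spec.test_size)
    test_x = (centers[test_labels] + offsets[test_groups]
              + rng.standard_normal((spec.test_size, spec.feature_dim)))
    test = ClientDataset(test_x, test_labels, client_id="test")
    return FederationManifest(clients, group_ids, test, spec)


# ---------------------------------------------------------------------------
# image mode
# ---------------------------------------------------------------------------


def _class_template(c: int, side: int) -> np.ndarray:
    """Deterministic geometric pattern for class c on a side x side canvas."""
    yy, xx = np.mgrid[0:side, 0:side]
    kind = c % 6
    period = 2 + c // 6  # later classes reuse patterns at higher frequency
    if kind == 0:  # horizontal bars
        img = (yy // period) % 2
    elif kind == 1:  # vertical bars
        img = (xx // period) % 2
    elif kind == 2:  # centered disk
        r = np.hypot(yy - (side - 1) / 2, xx - (side - 1) / 2)
        img = (r < side / (3 + c // 6)).astype(float)
    elif kind == 3:  # diagonal stripes
        img = ((xx + yy) // period) % 2
    elif kind == 4:  # checkerboard
        img = ((xx // period) + (yy // period)) % 2
    else:  # cross
        w = max(1, side // (6 + c // 6))
        mid = side // 2
        img = ((np.abs(yy - mid) < w) | (np.abs(xx - mid) < w)).astype(float)
    return img.astype(np.float64)


def generate_image_federation(spec: SyntheticSpec) -> FederationManifest:
    """Image federation: class-dependent geometric patterns on noisy
    backgrounds with group-dependent contrast and noise level; pixel values
    clipped to [0, 1].  ``spec.feature_dim`` is the image side (>= 8)."""
    side = spec.feature_dim
    if side < 8:
        raise ConfigurationError(f"image side must be >= 8, got {side}")
    rng = np.random.default_rng(spec.seed)
    templates = np.stack([_class_template(c, side) for c in range(spec.num_classes)])
    mixes = _group_label_mixes(rng, spec)

    g_max = max(spec.num_groups - 1, 1)

    def render(labels: np.ndarray, groups: np.ndarray) -> np.ndarray:
        contrast = 1.0 - 0.4 * (groups / g_max)  # group-dependent contrast
        noise_scale = spec.image_noise * (1.0 + groups / g_max)
        imgs = templates[labels] * contrast[:, None, None]
        imgs = imgs + noise_scale[:, None, None] * rng.standard_normal(imgs.shape)
        return np.clip(imgs, 0.0, 1.0)

    lo, hi = spec.samples_per_client
    clients, group_ids = [], []
    for k in range(spec.num_clients):
        g = k % spec.num_groups
        n = int(rng.integers(lo, hi + 1))
        labels = rng.choice(spec.num_classes, size=n, p=mixes[g])
        imgs = render(labels, np.full(n, g))
        clients.append(ClientDataset(imgs, labels, client_id=k))
        group_ids.append(g)

    test_labels = rng.choice(spec.num_classes, size=spec.test_size)
    test_groups = rng.integers(0, spec.num_groups, size=spec.test_size)
    test = ClientDataset(render(test_labels, test_groups), test_labels, client_id="test")
    return FederationManifest(clients, group_ids, test, spec)
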