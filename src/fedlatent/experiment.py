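"""Configuration-driven orchestration of the full simulation loop.

Phase A (proposed method only): each client trains a VAE from a common
broadcast initialization, encodes its data, and sends its latent signature
to the server; the server computes the pairwise Jensen-Shannon matrix,
thresholds it into groups, and selects group heads by latent variance.
Phase B: for each round the global model is broadcast, every client runs one
local SGD pass, and the server aggregates — two-level weighted aggregation
for the proposed method, sample-count weighting for the FedAvg baseline —
then evaluates the new global model on the held-out test set.

All randomness derives from one master seed through ``numpy.random
.SeedSequence`` spawning, so runs are reproducible and per-client streams
are independent; the derived seeds are recorded in the result.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import divergence_grouping as dg
from .aggregation import (AggregationConfig, compute_group_stats,
                          fedavg_aggregate, run_proposed_aggregation)
from .divergence_grouping import (DivergenceMatrix, GroupAssignment,
                                  GroupingConfig, assign_heads, form_groups,
                                  pairwise_divergence, suggest_threshold)
from .fl_core import (ClientConfig, ClientDataset, ConfigurationError,
                      ModelParameters, ModelSpec, build_model, evaluate_model,
                      local_update)
from .latent_signature import (LatentSignature, VAEConfig, encode_dataset,
                               summarize_signature, train_vae)
from .synthetic_data import (FederationManifest, SyntheticSpec,
                             generate_federation, generate_image_federation)

__all__ = [
    "ExperimentConfig",
    "RoundLog",
    "ExperimentResult",
    "run_experiment",
    "compute_signatures",
    "group_clients",
    "divergence_op_count",
]


@dataclass
class RoundLog:
    round: int
    global_loss: float
    global_accuracy: float
    group_weights: list[float] = field(default_factory=list)
    wall_time: float = 0.0  # informational only

    def __post_init__(self):
        if not 0.0 <= self.global_accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class ExperimentConfig:
    rounds: int = 100
    method: str = "proposed"
    model: ModelSpec = field(default_factory=lambda: ModelSpec(
        kind="dnn", input_shape=(8,), num_classes=3, hidden_width=64))
    client: ClientConfig = field(default_factory=ClientConfig)
    vae: VAEConfig = field(default_factory=VAEConfig)
    grouping: GroupingConfig | None = None  # None -> suggest threshold from data
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    image_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 1:
            raise ConfigurationError("rounds must be >= 1")
        if self.method not in ("proposed", "fedavg"):
            raise ConfigurationError(f"unknown method {self.method!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        if "model" in kwargs and isinstance(kwargs["model"], dict):
            m = dict(kwargs["model"])
            m["input_shape"] = tuple(m["input_shape"])
            kwargs["model"] = ModelSpec(**m)
        for key, ctor in (("client", ClientConfig), ("vae", VAEConfig),
                          ("aggregation", AggregationConfig),
                          ("synthetic", SyntheticSpec)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in kwargs[key].items()}
                kwargs[key] = ctor(**sub)
        if "grouping" in kwargs and isinstance(kwargs["grouping"], dict):
            kwargs["grouping"] = GroupingConfig(**kwargs["grouping"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ExperimentResult:
    logs: list[RoundLog]
    final_model: ModelParameters
    assignment: GroupAssignment | None
    signatures: dict | None
    divergence: DivergenceMatrix | None
    threshold: float | None
    seeds: dict
    audits: list[dict] = field(default_factory=list)

    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            {"round": lg.round, "global_loss": lg.global_loss,
             "global_accuracy": lg.global_accuracy,
             **{f"group_weight_{m}": w for m, w in enumerate(lg.group_weights)}}
            for lg in self.logs
        ]
        return pd.DataFrame(rows)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.metrics_frame().to_csv(directory / "metrics.csv", index=False)
        with (directory / "rounds.jsonl").open("w") as fh:
            for lg in self.logs:
                fh.write(json.dumps(dataclasses.asdict(lg)) + "\n")
        if self.assignment is not None:
            (directory / "groups.json").write_text(self.assignment.to_json())
        if self.divergence is not None:
            self.divergence.to_csv(directory / "divergence.csv")
        (directory / "seeds.json").write_text(json.dumps(self.seeds))
        if self.audits:
            with (directory / "weights.jsonl").open("w") as fh:
                for t, audit in enumerate(self.audits):
                    fh.write(json.dumps({"round": t, **audit}) + "\n")


def divergence_op_count(k: int) -> int:
    """Exact number of pairwise JSD evaluations for K clients: K(K-1)/2."""
    if k < 1:
        raise ValueError("K must be >= 1")
    return k * (k - 1) // 2


def _derive_seeds(master: int, num_clients: int) -> dict:
    """Counter-based seed splitting from the master seed.

    SeedSequence(master) spawns one child per role; children are independent
    streams regardless of client count, so adding clients never perturbs
    existing ones.  Integer seeds are recorded for the manifest."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(3 + 2 * num_clients)
    as_int = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return {
        "master": master,
        "data": as_int[0],
        "model_init": as_int[1],
        "vae_init": as_int[2],
        "vae_clients": as_int[3 : 3 + num_clients],
        "train_clients": as_int[3 + num_clients :],
    }


def compute_signatures(manifest: FederationManifest, vae_cfg: VAEConfig,
                       seeds: dict) -> dict:
    """Phase A per-client work: VAE training + encoding + signature.

    Every client starts from the same broadcast initialization
    (``seeds['vae_init']``) but trains with its own noise stream."""
    signatures = {}
    for ds, seed in zip(manifest.clients, seeds["vae_clients"]):
        cfg = replace(vae_cfg, seed=seed, init_seed=seeds["vae_init"])
        model, _, _ = train_vae(ds, cfg)
        latents = encode_dataset(model, ds)
        signatures[ds.client_id] = summarize_signature(latents, ds, cfg)
    return signatures


def group_clients(signatures: dict, grouping: GroupingConfig | None
                  ) -> tuple[GroupAssignment, DivergenceMatrix, float]:
    """Pairwise divergence, thresholding, and head selection."""
    ordered = [signatures[cid] for cid in sorted(signatures)]
    div = pairwise_divergence(ordered)
    threshold = grouping.threshold if grouping is not None else suggest_threshold(div)
    assignment = form_groups(div, GroupingConfig(threshold=threshold))
    assignment = assign_heads(assignment, signatures)
    return assignment, div, threshold


def run_experiment(cfg: ExperimentConfig,
                   manifest: FederationManifest | None = None) -> ExperimentResult:
    """Execute the full simulation and return per-round logs + final model."""
    seeds = _derive_seeds(cfg.seed, cfg.synthetic.num_clients)
    if manifest is None:
        spec = replace(cfg.synthetic, seed=seeds["data"])
        manifest = (generate_image_federation(spec) if cfg.image_mode
                    else generate_federation(spec))
    n_clients = manifest.num_clients
    if n_clients != len(seeds["train_clients"]):
        seeds = _derive_seeds(cfg.seed, n_clients)

    signatures = assignment = div = None
    threshold = None
    if cfg.method == "proposed":
        signatures = compute_signatures(manifest, cfg.vae, seeds)
        assignment, div, threshold = group_clients(signatures, cfg.grouping)
        stats = compute_group_stats(assignment, signatures)

    global_model = build_model(cfg.model, seeds["model_init"])
    logs: list[RoundLog] = []
    audits: list[dict] = []
    for t in range(cfg.rounds):
        t0 = time.perf_counter()
        local_models = {}
        for ds, base_seed in zip(manifest.clients, seeds["train_clients"]):
            # per (client, round) stream so batch order differs across rounds
            round_seed = int(
                np.random.SeedSequence([base_seed, t]).generate_state(1)[0] % (2**31))
            ccfg = replace(cfg.client, seed=round_seed)
            local_models[ds.client_id] = local_update(global_model, ds, ccfg, cfg.model)

        if cfg.method == "proposed":
            global_model, audit = run_proposed_aggregation(
                local_models, assignment, stats, cfg.aggregation)
            group_w = audit["group_weights"]
            audits.append(audit)
        else:
            ordered = [ds.client_id for ds in manifest.clients]
            global_model = fedavg_aggregate(
                [local_models[c] for c in ordered],
                [ds.n_samples for ds in manifest.clients])
            group_w = []

        loss, acc = evaluate_model(global_model, manifest.test_set, cfg.model)
        logs.append(RoundLog(round=t, global_loss=loss, global_accuracy=acc,
                             group_weights=list(group_w),
                             wall_time=time.perf_counter() - t0))

    return ExperimentResult(logs=logs, final_model=global_model,
                            assignment=assignment, signatures=signatures,
                            divergence=div, threshold=threshold, seeds=seeds,
                            audits=audits)
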