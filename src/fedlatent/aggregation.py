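"""Two-level weighted model aggregation plus the FedAvg baseline.

Within each group, client models are averaged with weights built from three
ratios — data volume n_k/n_m, label-class count l_k/l_m, and latent-space
variance d_k/d_m — mixed by coefficients (1-g-b), (1-a-g), (1-a-b) derived
from a simplex-constrained triple (a, b, g).  The constraint a + b + g = 1
makes the three coefficients themselves sum to 1, so the client weights in
each group form a convex combination and the global model's scale cannot
drift across rounds.  The same structure aggregates the group models into
the next global model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fl_core import ModelParameters
from .divergence_grouping import GroupAssignment
from .latent_signature import LatentSignature

__all__ = [
    "AggregationConfig",
    "GroupStats",
    "DegenerateGroupError",
    "compute_group_stats",
    "combination_weights",
    "global_weights",
    "aggregate_parameters",
    "run_proposed_aggregation",
    "fedavg_aggregate",
]


class DegenerateGroupError(ValueError):
    """A group (or the federation) has zero total volume/classes/variance."""


@dataclass(frozen=True)
class AggregationConfig:
    alpha: float = 1.0 / 3.0
    beta: float = 1.0 / 3.0
    gamma: float = 1.0 / 3.0
    per_group_overrides: Mapping[int, tuple[float, float, float]] | None = None

    def __post_init__(self):
        self._check(self.alpha, self.beta, self.gamma, "global")
        if self.per_group_overrides:
            for m, (a, b, g) in self.per_group_overrides.items():
                self._check(a, b, g, f"group {m}")

    @staticmethod
    def _check(a: float, b: float, g: float, where: str) -> None:
        for name, v in (("alpha", a), ("beta", b), ("gamma", g)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{where}: {name}={v} outside [0, 1]")
        if abs(a + b + g - 1.0) > 1e-9:
            raise ValueError(f"{where}: alpha+beta+gamma must equal 1, got {a + b + g}")

    def for_group(self, m: int) -> tuple[float, float, float]:
        if self.per_group_overrides and m in self.per_group_overrides:
            return tuple(self.per_group_overrides[m])
        return self.alpha, self.beta, self.gamma


@dataclass
class GroupStats:
    """Per-client (n, l, variance) plus per-group and global totals."""

    client: dict  # client_id -> (n, l, delta)
    group_totals: list[tuple[float, float, float]]  # aligned with assignment.groups
    global_totals: tuple[float, float, float]


def compute_group_stats(assignment: GroupAssignment,
                        signatures: Mapping[object, LatentSignature]) -> GroupStats:
    client = {}
    group_totals = []
    for g in assignment.groups:
        nm = lm = dm = 0.0
        for cid in g:
            try:
                sig = signatures[cid]
            except KeyError as exc:
                raise KeyError(f"no signature for client {cid!r}") from exc
            triple = (float(sig.sample_count), float(sig.label_class_count),
                      float(sig.variance))
            client[cid] = triple
            nm += triple[0]
            lm += triple[1]
            dm += triple[2]
        group_totals.append((nm, lm, dm))
    totals = tuple(float(sum(t[i] for t in group_totals)) for i in range(3))
    return GroupStats(client=client, group_totals=group_totals, global_totals=totals)


def _mixed_weights(parts: np.ndarray, totals: tuple[float, float, float],
                   abg: tuple[float, float, float], where: str) -> np.ndarray:
    """Shared weight formula for both aggregation levels.

    parts: (K, 3) rows of (n, l, delta); totals: their column sums."""
    a, b, g = abg
    n_tot, l_tot, d_tot = totals
    if n_tot <= 0 or l_tot <= 0 or d_tot <= 0:
        raise DegenerateGroupError(f"{where}: zero total in (n={n_tot}, l={l_tot}, d={d_tot})")
    coeff = np.array([1.0 - g - b, 1.0 - a - g, 1.0 - a - b])
    ratios = parts / np.array([n_tot, l_tot, d_tot])
    weights = ratios @ coeff
    return weights


def combination_weights(group: Sequence, stats: GroupStats, cfg: AggregationConfig,
                        group_index: int | None = None) -> dict:
    """Per-client weights for one group's combination aggregation.

    weight_k = (1-g-b) n_k/n_m + (1-a-g) l_k/l_m + (1-a-b) d_k/d_m with the
    group's (possibly overridden) coefficient triple; weights are
    non-negative and sum to 1."""
    members = list(group)
    parts = np.array([stats.client[cid] for cid in members])
    totals = tuple(parts.sum(axis=0))
    abg = cfg.for_group(group_index) if group_index is not None else (
        cfg.alpha, cfg.beta, cfg.gamma)
    w = _mixed_weights(parts, totals, abg, f"group {group_index}")
    return dict(zip(members, w))


def global_weights(stats: GroupStats, cfg: AggregationConfig) -> np.ndarray:
    """Per-group weights for the global aggregation (same formula, group level)."""
    parts = np.array(stats.group_totals)
    return _mixed_weights(parts, stats.global_totals, (cfg.alpha, cfg.beta, cfg.gamma),
                          "global")


def aggregate_parameters(models: Sequence[ModelParameters],
                         weights: Sequence[float]) -> ModelParameters:
    """Element-wise convex combination of same-layout parameter vectors."""
    if len(models) != len(weights):
        raise ValueError("one weight per model required")
    if not models:
        raise ValueError("nothing to aggregate")
    layout = models[0].layout
    for m in models[1:]:
        if m.layout != layout:
            raise ValueError("all models must share one layout")
    w = np.asarray(weights, dtype=np.float64)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()}, not 1")
    stacked = np.stack([m.values for m in models])
    return ModelParameters(w @ stacked, list(layout))


def run_proposed_aggregation(local_models: Mapping[object, ModelParameters],
                             assignment: GroupAssignment, stats: GroupStats,
                             cfg: AggregationConfig) -> tuple[ModelParameters, dict]:
    """Two-level aggregation over one round's local models.

    Per group: combination weights + weighted average (attributed to the
    group head in the audit record; numerically identical wherever computed).
    Then: global weights over the group models.  Returns the next global
    model and an audit dict with every weight used."""
    group_models = []
    audit_groups = []
    for m, g in enumerate(assignment.groups):
        cw = combination_weights(g, stats, cfg, group_index=m)
        members = list(g)
        model = aggregate_parameters([local_models[c] for c in members],
                                     [cw[c] for c in members])
        group_models.append(model)
        audit_groups.append({
            "group_index": m,
            "head": assignment.heads[m] if assignment.heads else None,
            "client_weights": {str(c): float(cw[c]) for c in members},
        })
    gw = global_weights(stats, cfg)
    new_global = aggregate_parameters(group_models, gw)
    audit = {"groups": audit_groups, "group_weights": [float(w) for w in gw]}
    return new_global, audit


def fedavg_aggregate(local_models: Sequence[ModelParameters],
                     sample_counts: Sequence[int]) -> ModelParameters:
    """FedAvg baseline: weights proportional to client sample counts."""
    counts = np.asarray(sample_counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("sample counts must be positive")
    return aggregate_parameters(list(local_models), counts / counts.sum())
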