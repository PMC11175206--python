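"""Jensen-Shannon divergence between client signatures and threshold grouping.

The server compares clients only through the probability histograms in their
latent signatures.  Pairwise Jensen-Shannon divergence (natural-log base, so
bounded by ln 2) fills a symmetric K x K matrix; an edge is drawn between two
clients whenever their divergence falls below a threshold, and the connected
components of that graph are the groups.  Each group's head is the member
with the largest latent-space variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .fl_core import ConfigurationError
from .latent_signature import LatentSignature

__all__ = [
    "DivergenceMatrix",
    "GroupingConfig",
    "GroupAssignment",
    "InfiniteDivergenceError",
    "kl_divergence",
    "js_divergence",
    "pairwise_divergence",
    "form_groups",
    "select_group_head",
    "assign_heads",
    "suggest_threshold",
    "reset_jsd_counter",
    "jsd_evaluation_count",
]

LN2 = float(np.log(2.0))

# instrumentation: number of js_divergence evaluations since the last reset,
# used to verify the O(K^2) pairwise cost empirically
_JSD_EVALUATIONS = 0


def reset_jsd_counter() -> None:
    global _JSD_EVALUATIONS
    _JSD_EVALUATIONS = 0


def jsd_evaluation_count() -> int:
    return _JSD_EVALUATIONS


class InfiniteDivergenceError(ValueError):
    """KL(p || q) is infinite because q vanishes where p has mass."""


def _as_distribution(p) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("probability vector must be 1-D and non-empty")
    if np.any(p < 0):
        raise ValueError("probability vector has negative entries")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"probability vector sums to {total}, not 1")
    return p / total


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence sum_i p_i ln(p_i/q_i), with 0 ln(0/x) = 0."""
    p = _as_distribution(p)
    q = _as_distribution(q)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.size} vs {q.size}")
    support = p > 0
    if np.any(q[support] == 0):
        raise InfiniteDivergenceError("q has zero mass where p is positive")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence in nats: 0.5 KL(p||m) + 0.5 KL(q||m), m=(p+q)/2."""
    global _JSD_EVALUATIONS
    _JSD_EVALUATIONS += 1
    p = _as_distribution(p)
    q = _as_distribution(q)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.size} vs {q.size}")
    m = 0.5 * (p + q)
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


@dataclass
class DivergenceMatrix:
    values: np.ndarray
    client_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.client_ids = list(self.client_ids)
        k = len(self.client_ids)
        if self.values.shape != (k, k):
            raise ValueError(f"matrix shape {self.values.shape} does not match {k} clients")
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise ValueError("divergence matrix must be symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if self.values.min() < 0 or self.values.max() > LN2 + 1e-12:
            raise ValueError("entries must lie in [0, ln 2]")

    @property
    def n_clients(self) -> int:
        return len(self.client_ids)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_clients, k=1)
        return self.values[iu]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.client_ids,
                     columns=self.client_ids).to_csv(path)


@dataclass(frozen=True)
class GroupingConfig:
    threshold: float
    linkage: str = "connected_components"

    def __post_init__(self):
        if not 0 < self.threshold < LN2:
            raise ConfigurationError(f"threshold must lie in (0, ln 2), got {self.threshold}")
        if self.linkage != "connected_components":
            raise ConfigurationError(f"unsupported linkage {self.linkage!r}")


@dataclass
class GroupAssignment:
    """Disjoint client groups plus, once selected, one head per group."""

    groups: list[list]
    heads: list | None = None

    def __post_init__(self):
        seen = set()
        for g in self.groups:
            if not g:
                raise ValueError("groups must be non-empty")
            for cid in g:
                if cid in seen:
                    raise ValueError(f"client {cid!r} appears in more than one group")
                seen.add(cid)
        if self.heads is not None:
            if len(self.heads) != len(self.groups):
                raise ValueError("one head per group required")
            for head, g in zip(self.heads, self.groups):
                if head not in g:
                    raise ValueError(f"head {head!r} is not a member of its group")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, client_id) -> int:
        for m, g in enumerate(self.groups):
            if client_id in g:
                return m
        raise KeyError(client_id)

    def labels(self, client_ids: Sequence) -> np.ndarray:
        """Group index per client in the given order (for partition comparison)."""
        return np.array([self.group_of(c) for c in client_ids])

    def to_json(self) -> str:
        payload = [
            {"group_index": m, "clients": list(g),
             "head": None if self.heads is None else self.heads[m]}
            for m, g in enumerate(self.groups)
        ]
        return json.dumps(payload)


def pairwise_divergence(signatures: Sequence[LatentSignature]) -> DivergenceMatrix:
    """Symmetric JSD matrix over K signatures using K(K-1)/2 evaluations."""
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    lengths = {len(s.histogram) for s in signatures}
    if len(lengths) != 1:
        raise ConfigurationError(f"mixed histogram lengths: {sorted(lengths)}")
    k = len(signatures)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = js_divergence(signatures[i].histogram, signatures[j].histogram)
            values[i, j] = values[j, i] = min(d, LN2)
    return DivergenceMatrix(values, [s.client_id for s in signatures])


def form_groups(div: DivergenceMatrix, cfg: GroupingConfig) -> GroupAssignment:
    """Threshold grouping: edge (k, j) iff divergence < threshold, groups are
    the connected components.  Clients with no sub-threshold neighbor become
    singleton groups.  Groups are ordered by their smallest member id."""
    graph = nx.Graph()
    graph.add_nodes_from(div.client_ids)
    k = div.n_clients
    for i in range(k):
        for j in range(i + 1, k):
            if div.values[i, j] < cfg.threshold:
                graph.add_edge(div.client_ids[i], div.client_ids[j])
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: c[0])
    return GroupAssignment(groups=components)


def select_group_head(group: Sequence,
                      signatures: Mapping[object, LatentSignature]):
    """The member with the largest latent variance; ties -> lowest client id."""
    members = list(group)
    if not members:
        raise ValueError("group is empty")
    return max(sorted(members), key=lambda cid: (signatures[cid].variance,))


def assign_heads(assignment: GroupAssignment,
                 signatures: Mapping[object, LatentSignature]) -> GroupAssignment:
    heads = [select_group_head(g, signatures) for g in assignment.groups]
    return GroupAssignment(groups=[list(g) for g in assignment.groups], heads=heads)


def suggest_threshold(div: DivergenceMatrix) -> float:
    """Threshold between the two modes of the pairwise-divergence histogram.

    With well-separated client populations the pairwise JSD values are
    bimodal: a tight mode of small within-group values and a broad mode of
    larger between-group values.  Because divergences are scale-like, the
    split is computed in the log domain: an Otsu-style two-cluster split
    maximizes the between-cluster variance of the log values, and the
    returned threshold is the geometric midpoint across the split.  The
    result is clipped into (0, ln 2)."""
    vals = np.sort(div.upper_triangle())
    if vals.size < 2:
        return float(np.clip(vals[0] if vals.size else LN2 / 2, 1e-6, LN2 - 1e-6))
    logv = np.log(np.maximum(vals, 1e-12))
    n = logv.size
    best, split = -np.inf, 1
    for i in range(1, n):
        a, b = logv[:i], logv[i:]
        between = (a.size * b.size / n**2) * (a.mean() - b.mean()) ** 2
        if between > best:
            best, split = between, i
    mid = np.exp(0.5 * (logv[split - 1] + logv[split]))
    return float(np.clip(mid, 1e-6, LN2 - 1e-6))
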