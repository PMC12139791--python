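"""Network strength scoring and the canonical-network connectivity grid.

Network strength is the mean Fisher-z connectivity over the upper-triangle
edges of a binary mask; edges touching an invalid node are NaN and dropped
from the mean. A strength with zero usable edges is NaN — an explicit
"undefined" marker, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from connshift.io import ConnMatrix, EdgeMask, ValidationError


def network_strength(conn: ConnMatrix, mask: EdgeMask) -> float:
    """Mean Fisher-z over the mask's edges (NaN edges dropped; NaN if none usable)."""
    value, _ = network_strength_with_count(conn, mask)
    return value


def network_strength_with_count(conn: ConnMatrix, mask: EdgeMask) -> tuple[float, int]:
    if conn.values.shape != mask.matrix.shape:
        raise ValidationError(
            f"shape mismatch: conn {conn.values.shape} vs mask {mask.matrix.shape}")
    ii, jj = mask.edge_indices()
    vals = conn.values[ii, jj]
    usable = ~np.isnan(vals)
    n_used = int(usable.sum())
    if n_used == 0:
        return float("nan"), 0
    return float(vals[usable].mean()), n_used


@dataclass(frozen=True)
class NetworkStrengthResult:
    """High/low mask strengths for one connectome; ``diff`` is high − low."""

    high: float
    low: float
    n_edges_used_high: int
    n_edges_used_low: int

    @property
    def diff(self) -> float:
        return self.high - self.low


def attention_strengths(conn: ConnMatrix, high_mask: EdgeMask, low_mask: EdgeMask) -> NetworkStrengthResult:
    """Score one connectome against the high- and low-attention masks."""
    high, n_high = network_strength_with_count(conn, high_mask)
    low, n_low = network_strength_with_count(conn, low_mask)
    return NetworkStrengthResult(high=high, low=low,
                                 n_edges_used_high=n_high, n_edges_used_low=n_low)


def attention_diff(result: NetworkStrengthResult) -> float:
    """High- minus low-attention network strength (NaN propagates)."""
    return result.diff


@dataclass(frozen=True)
class SaCpmModel:
    """Linear model mapping the high−low strength difference to predicted d'.

    The published coefficient/intercept live outside this package; defaults
    are identity placeholders and real analyses must supply their own.
    """

    coefficient: float = 1.0
    intercept: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.coefficient) and np.isfinite(self.intercept)):
            raise ValidationError("saCPM model parameters must be finite")


def sacpm_predict(diff: float, model: SaCpmModel) -> float:
    """Predicted task sensitivity: coefficient × (high − low) + intercept."""
    return model.coefficient * diff + model.intercept


@dataclass(frozen=True)
class CanonicalAssignment:
    """Node → canonical-network label map (eight resting-state networks)."""

    labels: tuple[str, ...]           # length n_nodes
    networks: tuple[str, ...]         # grid order

    def __post_init__(self):
        unknown = set(self.labels) - set(self.networks)
        if unknown:
            raise ValidationError(f"labels not in network list: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def nodes_of(self, network: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == network], dtype=int)


def canonical_grid(conn: ConnMatrix, assign: CanonicalAssignment) -> np.ndarray:
    """K×K mean-connectivity grid over canonical networks.

    Cell (A, A) is the mean Fisher-z over unordered within-A node pairs;
    cell (A, B) the mean over pairs spanning A and B. NaN edges are dropped;
    a diagonal cell for a network with < 2 nodes is NaN. The grid is symmetric
    and invariant to relabeling/permutation of nodes.
    """
    if conn.n_nodes != assign.n_nodes:
        raise ValidationError(
            f"assignment covers {assign.n_nodes} nodes, connectome has {conn.n_nodes}")
    k = len(assign.networks)
    grid = np.full((k, k), np.nan)
    node_sets = [assign.nodes_of(net) for net in assign.networks]
    for a in range(k):
        for b in range(a, k):
            na, nb = node_sets[a], node_sets[b]
            if a == b:
                if len(na) < 2:
                    continue
                sub = conn.values[np.ix_(na, na)]
                vals = sub[np.triu_indices(len(na), k=1)]
            else:
                if len(na) == 0 or len(nb) == 0:
                    continue
                vals = conn.values[np.ix_(na, nb)].ravel()
            usable = vals[~np.isnan(vals)]
            if usable.size:
                grid[a, b] = grid[b, a] = float(usable.mean())
    return grid
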