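"""Hypergeometric edge-set overlap tests.

Whether two brain networks (binary edge masks over the same parcellation)
share more edges than expected by chance: with M possible edges in total, one
network of K edges and another of n edges, the overlap count X is
Hypergeometric(M, K, n) under random draws without replacement. The test
reports the upper tail P(X ≥ x) = 1 − CDF(x − 1) — the convention that
reproduces the published worked values — via scipy's log-stable survival
function. The literal "1 − CDF(x)" (strictly-greater) convention is
available with ``inclusive=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from scipy.stats import hypergeom

from connshift.io import EdgeMask, ValidationError


def total_edges(n_nodes: int) -> int:
    """Number of possible edges (unordered node pairs): n(n−1)/2."""
    if n_nodes < 2:
        raise ValidationError(f"need at least 2 nodes, got {n_nodes}")
    return n_nodes * (n_nodes - 1) // 2


def overlap_count(mask_a: EdgeMask, mask_b: EdgeMask) -> int:
    """Number of edges present in both masks."""
    if mask_a.n_nodes != mask_b.n_nodes:
        raise ValidationError(
            f"mask sizes differ: {mask_a.n_nodes} vs {mask_b.n_nodes}")
    both = mask_a.matrix & mask_b.matrix
    return int(both.sum()) // 2


def hypergeom_overlap_p(x: int, K: int, n: int, M: int, inclusive: bool = True) -> float:
    """Upper-tail overlap probability under Hypergeometric(M, K, n).

    ``inclusive`` (default) gives P(X ≥ x); ``inclusive=False`` the literal
    P(X > x) = 1 − CDF(x).
    """
    if not (0 <= K <= M and 0 <= n <= M):
        raise ValidationError(f"need 0 <= K, n <= M (K={K}, n={n}, M={M})")
    if x < 0 or x > min(K, n):
        raise ValidationError(f"infeasible overlap x={x} for K={K}, n={n}")
    k = x - 1 if inclusive else x
    return float(hypergeom.sf(k, M, K, n))


def round3(p: float) -> float:
    """Half-up rounding to 3 decimals, matching printed-table conventions."""
    return float(Decimal(repr(p)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OverlapTest:
    """One directional mask-pair overlap test."""

    label_a: str
    label_b: str
    x: int    # overlapping edges
    K: int    # edges in mask A
    n: int    # edges in mask B
    M: int    # total possible edges
    p: float  # upper-tail P(X >= x)

    def __post_init__(self):
        if not (0 <= self.x <= min(self.K, self.n)):
            raise ValidationError("overlap count outside feasible range")
        if self.K > self.M or self.n > self.M:
            raise ValidationError("mask edge counts exceed total possible edges")


def overlap_table(mask_pairs: Sequence[tuple[EdgeMask, EdgeMask]],
                  M: int | None = None, inclusive: bool = True) -> list[OverlapTest]:
    """Overlap tests for a list of directional mask pairs.

    ``M`` defaults to the masks' own total edge count; pass the full-atlas
    value (e.g. 35,778 for 268 nodes) when masks live on a larger
    parcellation than they were cropped from.
    """
    out = []
    for a, b in mask_pairs:
        m = M if M is not None else total_edges(a.n_nodes)
        x = overlap_count(a, b)
        out.append(OverlapTest(label_a=a.label, label_b=b.label,
                               x=x, K=a.edge_count, n=b.edge_count, M=m,
                               p=hypergeom_overlap_p(x, a.edge_count, b.edge_count, m,
                                                     inclusive=inclusive)))
    return out
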