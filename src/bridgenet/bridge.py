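"""Bridge expected influence and cross-community edge accounting.

With nodes partitioned into two theory-given communities (personality
traits vs. anxiety/depression symptoms), the bridge expected influence
(BEI) of a node is the signed sum of its edge weights to nodes of the other
community — the one-step variant only.  A positive BEI marks a node whose
net connectivity transmits activation into the other community; a negative
BEI marks net protective connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .network import ZERO_TOL, PartialCorrelationNetwork


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as printed percentages use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CrossEdgeSummary:
    """Whole-network vs. cross-community edge counts.

    ``percent_bridge`` is 100 * n_bridge_edges / n_nonzero_edges rounded
    half-up to two decimals, or None for an empty network.
    """

    n_nonzero_edges: int
    n_bridge_edges: int
    percent_bridge: float | None
    bridge_edges: pd.DataFrame  # node_i, node_j, weight; sorted by |weight| desc


def _check_partition(
    net: PartialCorrelationNetwork, partition: dict[str, str]
) -> np.ndarray:
    labels = []
    for nid in net.node_ids:
        if nid not in partition:
            raise ValidationError(f"node {nid!r} has no community label")
        labels.append(partition[nid])
    return np.asarray(labels)


def bridge_expected_influence(
    net: PartialCorrelationNetwork, partition: dict[str, str] | None = None
) -> pd.DataFrame:
    """One-step bridge expected influence per node, in network node order.

    BEI(i) = sum over j in the other community of W_ij.
    """
    partition = partition if partition is not None else net.community
    labels = _check_partition(net, partition)
    cross = labels[:, None] != labels[None, :]
    bei = (net.W * cross).sum(axis=1)
    return pd.DataFrame(
        {"node": list(net.node_ids), "community": labels, "bei": bei}
    )


def cross_community_edges(
    net: PartialCorrelationNetwork, partition: dict[str, str] | None = None
) -> CrossEdgeSummary:
    """Count nonzero and bridge edges and list the bridges by |weight|.

    Edges are upper-triangle entries with |w| > 1e-10.  Bridge edges are
    sorted by descending magnitude, ties broken by node order.
    """
    partition = partition if partition is not None else net.community
    labels = _check_partition(net, partition)
    rows = []
    n_nonzero = 0
    n_bridge = 0
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = net.W[i, j]
            if abs(w) > ZERO_TOL:
                n_nonzero += 1
                if labels[i] != labels[j]:
                    n_bridge += 1
                    rows.append((net.node_ids[i], net.node_ids[j], w, i, j))
    edges = pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "_i", "_j"])
    edges["_abs"] = edges["weight"].abs() if len(edges) else []
    edges = edges.sort_values(
        ["_abs", "_i", "_j"], ascending=[False, True, True]
    ).drop(columns=["_abs", "_i", "_j"]).reset_index(drop=True)
    percent = (
        round_half_up(100.0 * n_bridge / n_nonzero) if n_nonzero > 0 else None
    )
    return CrossEdgeSummary(
        n_nonzero_edges=n_nonzero,
        n_bridge_edges=n_bridge,
        percent_bridge=percent,
        bridge_edges=edges,
    )
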