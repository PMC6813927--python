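"""Guide-gene subnetwork extraction from the topological overlap matrix.

Guide genes (e.g. orthologs of known meiotic genes) seed a subnetwork of
all genes whose TOM similarity to at least one guide exceeds a weight
threshold; edges among the recruited nodes above the threshold are kept so
that neighbor–neighbor connections remain visible.  Hub strength of a node
is its direct-edge count and the percentage of subnetwork nodes it touches
(denominator includes the node itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io import write_edge_file
from .network import ModulePartition, TOMMatrix

__all__ = ["Subnetwork", "extract_guide_subnetwork", "hub_connectivity"]


@dataclass
class Subnetwork:
    nodes: list[str]
    roles: dict[str, str]  # guide / neighbor
    edges: list[tuple[str, str, float]]  # gene_i < gene_j, weight
    weight_threshold: float
    modules: dict[str, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        if node not in self.roles:
            raise KeyError(f"node {node!r} not in subnetwork")
        return sum(1 for a, b, _ in self.edges if node in (a, b))

    def write_edges(self, path) -> None:
        write_edge_file(self.edges, path)


def extract_guide_subnetwork(
    tom: TOMMatrix,
    partition: ModulePartition | None,
    guides: Sequence[str],
    weight_min: float = 0.05,
    guide_edges_only: bool = False,
) -> Subnetwork:
    """Subnetwork of genes connected to guide genes above a TOM threshold.

    Nodes are the guides plus every gene with TOM > weight_min to >= 1
    guide; edges are all node pairs above the threshold (only guide-touching
    edges when ``guide_edges_only``).  Ordering is deterministic: guides
    first (input order), then neighbors lexicographically.
    """
    if not 0.0 <= weight_min < 1.0:
        raise ValueError("weight_min must be in [0, 1)")
    sim = tom.similarity
    present = [g for g in guides if g in sim.index]
    if not present:
        raise ValueError("no guide gene present in the network")
    guide_set = list(dict.fromkeys(present))
    sub = sim.loc[guide_set]
    neighbor_mask = (sub > weight_min).any(axis=0)
    neighbors = sorted(g for g in sim.columns[neighbor_mask] if g not in guide_set)
    nodes = guide_set + neighbors
    roles = {g: ("guide" if g in guide_set else "neighbor") for g in nodes}
    edges = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if guide_edges_only and roles[a] != "guide" and roles[b] != "guide":
                continue
            w = float(sim.at[a, b])
            if w > weight_min:
                edges.append((a, b, w))
    modules = (
        {g: partition[g] for g in nodes if g in partition.labels.index}
        if partition is not None
        else {}
    )
    return Subnetwork(nodes, roles, edges, float(weight_min), modules)


def hub_connectivity(subnetwork: Subnetwork, node: str) -> tuple[int, float]:
    """Direct-edge count of a node and % of subnetwork nodes it connects to.

    The percentage uses the full node count (including the node itself) as
    denominator and is rounded to 1 decimal.
    """
    degree = subnetwork.degree(node)
    percent = round(100.0 * degree / subnetwork.n_nodes, 1)
    return degree, percent
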