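"""Node-level and network-level topology statistics.

All statistics are defined on the :class:`~netcomorbid.model.SimpleGraph`
projection of a typed multigraph: betweenness centrality (unweighted,
undirected, endpoints excluded), crosstalk specificity (CTS), and the
network summary triple (average neighbors, density, Freeman degree
centralization).

Conventions
-----------
density
    ``avg_neighbors / (2 * (n_nodes - 1))`` — half the usual undirected
    convention.  This is the convention under which the published summary
    pairs (n=430, k̄=84.764 → 0.1) and (n=332, k̄=4.322 → 0.007) are both
    reproduced, so it is adopted throughout; values therefore live in
    [0, 0.5].
centralization
    Freeman degree centralization as popularized by Cytoscape's
    NetworkAnalyzer: ``(n / (n - 2)) * (k_max - k̄) / (n - 1)`` on simple
    degrees.  1 for a star, 0 for any degree-regular graph.
CTS
    ``K_i / M_i`` — a gene's neighbor count inside the analyzed subnetwork
    divided by its neighbor count in the global network.  Values in (0, 1];
    1 means every global neighbor of the gene lies inside the subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence, Union

import networkx as nx

from .model import GeneNetwork, NetworkValidationError, SimpleGraph, project_simple

__all__ = [
    "CentralityRecord",
    "CTSRecord",
    "NetworkSummary",
    "betweenness",
    "crosstalk_specificity",
    "network_summary",
    "density_from_avg_neighbors",
    "centralization_from_degrees",
    "hub_ranking",
]


@dataclass(frozen=True, slots=True)
class CentralityRecord:
    gene: str
    betweenness_raw: float
    betweenness_normalized: float

    @property
    def score(self) -> float:
        return self.betweenness_raw


@dataclass(frozen=True, slots=True)
class CTSRecord:
    gene: str
    K: int
    M: int

    def __post_init__(self) -> None:
        if not 0 < self.K <= self.M:
            raise NetworkValidationError(
                f"CTS requires 0 < K <= M, got K={self.K}, M={self.M} for {self.gene}"
            )

    @property
    def cts(self) -> float:
        return self.K / self.M

    @property
    def score(self) -> float:
        return self.cts


@dataclass(frozen=True, slots=True)
class NetworkSummary:
    name: str
    n_nodes: int
    n_interactions: int
    n_pairs: int
    avg_neighbors: float
    density: float
    centralization: float


def betweenness(g: SimpleGraph, normalized: bool = False) -> list[CentralityRecord]:
    """Betweenness centrality of every node of ``g``.

    The raw score of node ``v`` is the sum over unordered pairs ``{s, t}``
    (``s != t != v``) of the fraction of shortest ``s``–``t`` paths passing
    through ``v``; disconnected pairs contribute zero and endpoints never
    accrue credit for their own paths.  The normalized score divides by
    ``(n-1)(n-2)/2``.  Graphs with fewer than 3 nodes score zero everywhere.
    Records are returned sorted by gene symbol.
    """
    n = g.n_nodes
    if n < 3:
        return [CentralityRecord(v, 0.0, 0.0) for v in sorted(g.nodes)]
    raw = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    denom = (n - 1) * (n - 2) / 2
    return [
        CentralityRecord(v, raw[v], raw[v] / denom) for v in sorted(g.nodes)
    ]


def crosstalk_specificity(
    sub: SimpleGraph, global_g: SimpleGraph
) -> list[CTSRecord]:
    """CTS = K/M for every node of ``sub`` against ``global_g``.

    ``sub`` must be a subnetwork of ``global_g``: every node and pair of
    ``sub`` must exist in the global graph, and every scored node must have
    at least one global neighbor.
    """
    missing = sub.nodes - global_g.nodes
    if missing:
        raise NetworkValidationError(
            f"genes absent from global network: {sorted(missing)}"
        )
    stray = sub.pairs - global_g.pairs
    if stray:
        raise NetworkValidationError(
            f"pairs absent from global network (not a subnetwork): {sorted(stray)[:5]}"
        )
    sub_deg = sub.degrees()
    records = []
    for gene in sorted(sub.nodes):
        m = global_g.degree(gene)
        if m == 0:
            raise NetworkValidationError(
                f"gene {gene} has no neighbors in the global network"
            )
        k = sub_deg[gene]
        if k == 0:
            # isolated within the subnetwork: CTS undefined (K must be > 0)
            continue
        records.append(CTSRecord(gene, K=k, M=m))
    return records


def density_from_avg_neighbors(n_nodes: int, avg_neighbors: float) -> float:
    """Density under the adopted convention ``k̄ / (2 (n - 1))``."""
    if n_nodes < 2:
        return 0.0
    return avg_neighbors / (2 * (n_nodes - 1))


def centralization_from_degrees(degrees: Sequence[int]) -> float:
    """Freeman degree centralization ``(n/(n-2)) * (k_max - k̄)/(n - 1)``."""
    n = len(degrees)
    if n < 3:
        return 0.0
    k_max = max(degrees)
    k_bar = sum(degrees) / n
    return (n / (n - 2)) * (k_max - k_bar) / (n - 1)


def network_summary(net: Union[GeneNetwork, SimpleGraph]) -> NetworkSummary:
    """Summary statistics of a network (on its simple projection)."""
    if isinstance(net, GeneNetwork):
        simple = project_simple(net)
        n_interactions = net.n_interactions
        name = net.name
    else:
        simple = net
        n_interactions = net.n_pairs
        name = net.provenance
    n = simple.n_nodes
    avg = 2 * simple.n_pairs / n if n else 0.0
    return NetworkSummary(
        name=name,
        n_nodes=n,
        n_interactions=n_interactions,
        n_pairs=simple.n_pairs,
        avg_neighbors=avg,
        density=density_from_avg_neighbors(n, avg),
        centralization=centralization_from_degrees(list(simple.degrees().values())),
    )


def hub_ranking(
    records: Sequence[Union[CentralityRecord, CTSRecord]], top_k: int
) -> list[str]:
    """Top genes by score, descending; ties broken lexicographically.

    ``top_k`` larger than the record list returns the full ranking.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")

    def sort_key(r):
        score = r.score
        if isinstance(r, CTSRecord):
            score = Fraction(r.K, r.M)  # exact tie detection
        return (-score, r.gene)

    ordered = sorted(records, key=sort_key)
    return [r.gene for r in ordered[:top_k]]
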