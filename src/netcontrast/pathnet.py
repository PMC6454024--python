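"""Merged pathway networks and their topology statistics.

Pathways enter as node membership (GMT) plus undirected interaction edges
(SIF). Every pathway containing at least one DE gene is selected, and the
selected pathways are merged into one simple undirected graph: nodes are
gene products, edges are deduplicated functional interactions. Members
with no incident edge are kept aside as singletons and excluded from
degree statistics. Hubs are nodes with degree strictly greater than a
threshold (default 20); neighborhood connectivity is the mean degree of a
node's neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from netcontrast import io as ncio


@dataclass
class PathwayCollection:
    """Named pathways: per pathway a member set and intra-pathway edges.

    Edge endpoints always belong to the same pathway; self-loops are
    dropped at load. Because the on-disk SIF does not record which pathway
    an edge came from, equality is defined on memberships plus the
    deduplicated edge union (which determines the merged network).
    """

    members: dict[str, set[str]] = field(default_factory=dict)
    edges: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, edge_set in self.edges.items():
            if name not in self.members:
                raise ValueError(f"edges for unknown pathway {name!r}")
            cleaned = set()
            for a, b in edge_set:
                if a == b:
                    continue  # self-loop
                if a not in self.members[name] or b not in self.members[name]:
                    raise ValueError(
                        f"edge ({a}, {b}) endpoints not both members of pathway {name!r}"
                    )
                cleaned.add(tuple(sorted((a, b))))
            self.edges[name] = cleaned
        for name in self.members:
            self.edges.setdefault(name, set())

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.members)

    def edge_union(self) -> set[tuple[str, str]]:
        union: set[tuple[str, str]] = set()
        for edge_set in self.edges.values():
            union |= edge_set
        return union

    def node_union(self) -> set[str]:
        nodes: set[str] = set()
        for members in self.members.values():
            nodes |= members
        return nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCollection):
            return NotImplemented
        return self.members == other.members and self.edge_union() == other.edge_union()

    # -- persistence --------------------------------------------------------

    def write(self, gmt_path, sif_path) -> None:
        ncio.write_gmt(self.members, gmt_path)
        ncio.write_sif(self.edge_union(), sif_path)

    @classmethod
    def read(cls, gmt_path, sif_path) -> "PathwayCollection":
        members = ncio.read_gmt(gmt_path)
        edge_union, singles = ncio.read_sif(sif_path)
        if singles:
            raise ncio.FormatError("pathway SIF must not contain singleton lines")
        edges: dict[str, set[tuple[str, str]]] = {name: set() for name in members}
        for a, b in edge_union:
            for name, mem in members.items():
                if a in mem and b in mem:
                    edges[name].add((a, b))
        return cls(members=members, edges=edges)


@dataclass
class MergedNetwork:
    """Deduplicated union graph with node annotations.

    ``graph`` holds the connected part (every node has >= 1 edge);
    ``singletons`` are members that had no incident edge and are excluded
    from degree statistics. Node attributes after annotation: de_status,
    degree, is_hub, neighborhood_connectivity.
    """

    graph: nx.Graph
    singletons: set[str] = field(default_factory=set)
    hub_threshold: int | None = None

    def check_invariants(self) -> None:
        assert sum(d for _, d in self.graph.degree()) == 2 * self.graph.number_of_edges()
        assert not any(self.graph.has_edge(n, n) for n in self.graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def hubs(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("is_hub")}

    def de_nodes(self) -> set[str]:
        return {
            n
            for n, d in self.graph.nodes(data=True)
            if d.get("de_status", "none") != "none"
        }

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": n,
                "de_status": d.get("de_status", "none"),
                "degree": d.get("degree", self.graph.degree(n)),
                "is_hub": bool(d.get("is_hub", False)),
                "neighborhood_connectivity": d.get("neighborhood_connectivity", np.nan),
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows).set_index("node") if rows else pd.DataFrame(
            columns=["de_status", "degree", "is_hub", "neighborhood_connectivity"]
        ).rename_axis("node")

    def summary(self) -> dict[str, int]:
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "n_singletons": len(self.singletons),
            "n_hubs": len(self.hubs()),
            "n_de_nodes": len(self.de_nodes()),
        }


def select_pathways(collection: PathwayCollection, de_genes: set[str]) -> PathwayCollection:
    """Subset to pathways whose member set intersects the DE gene set."""
    if not de_genes:
        warnings.warn("empty DE gene set: no pathway will be selected", stacklevel=2)
    keep = [name for name, mem in collection.members.items() if mem & de_genes]
    return PathwayCollection(
        members={name: set(collection.members[name]) for name in keep},
        edges={name: set(collection.edges[name]) for name in keep},
    )


def merge_network(selected: PathwayCollection) -> MergedNetwork:
    """Union of selected pathways as one simple graph plus singleton set."""
    graph = nx.Graph()
    graph.add_edges_from(selected.edge_union())
    singletons = selected.node_union() - set(graph.nodes)
    net = MergedNetwork(graph=graph, singletons=singletons)
    net.check_invariants()
    return net


def set_de_status(net: MergedNetwork, status: dict[str, str] | set[str]) -> MergedNetwork:
    """Attach de_status to every node; a plain set marks those genes "up"."""
    if isinstance(status, set):
        status = {g: "up" for g in status}
    for node in net.graph.nodes:
        net.graph.nodes[node]["de_status"] = status.get(node, "none")
    return net


def annotate_topology(net: MergedNetwork, hub_threshold: int = 20) -> MergedNetwork:
    """Set degree, is_hub (degree strictly > threshold) and neighborhood connectivity."""
    graph = net.graph
    for node in graph.nodes:
        deg = graph.degree(node)
        graph.nodes[node]["degree"] = deg
        graph.nodes[node]["is_hub"] = deg > hub_threshold
        neighbor_degrees = [graph.degree(m) for m in graph.neighbors(node)]
        graph.nodes[node]["neighborhood_connectivity"] = (
            float(np.mean(neighbor_degrees)) if neighbor_degrees else 0.0
        )
    net.hub_threshold = hub_threshold
    net.check_invariants()
    return net


def exclude_gene_module(net: MergedNetwork, gene_list) -> MergedNetwork:
    """Remove a self-contained gene module (e.g. a ribosomal complex).

    Listed nodes and their incident edges are removed; nodes left with no
    edge move to the singleton set; degrees and hub flags are recomputed.
    Absent genes trigger a warning, not an error.
    """
    gene_list = list(gene_list)
    present = [g for g in gene_list if g in net.graph or g in net.singletons]
    absent = sorted(set(gene_list) - set(present))
    if absent:
        warnings.warn(f"genes not in network, ignored: {absent}", stacklevel=2)
    graph = net.graph.copy()
    graph.remove_nodes_from([g for g in present if g in graph])
    singletons = (net.singletons - set(present)) | {
        n for n in graph.nodes if graph.degree(n) == 0
    }
    graph.remove_nodes_from([n for n in list(graph.nodes) if graph.degree(n) == 0])
    out = MergedNetwork(graph=graph, singletons=singletons)
    if net.hub_threshold is not None:
        annotate_topology(out, hub_threshold=net.hub_threshold)
    out.check_invariants()
    return out


@dataclass
class EcdfCurve:
    """Right-continuous empirical CDF over a group's node degrees."""

    values: np.ndarray  # sorted degree values (with repeats)
    fractions: np.ndarray  # cumulative fractions, ending at 1

    def evaluate(self, x: float) -> float:
        return float(np.searchsorted(self.values, x, side="right")) / len(self.values)

    def check_invariants(self) -> None:
        assert np.all(np.diff(self.fractions) >= 0)
        assert np.isclose(self.fractions[-1], 1.0)


def degree_ecdf(net: MergedNetwork, group: str = "DE") -> EcdfCurve:
    """ECDF of degrees for the DE or non-DE node group of the connected graph."""
    if group not in ("DE", "non-DE"):
        raise ValueError("group must be 'DE' or 'non-DE'")
    want_de = group == "DE"
    degrees = np.sort(
        [
            d
            for n, d in net.graph.degree()
            if (net.graph.nodes[n].get("de_status", "none") != "none") == want_de
        ]
    )
    if len(degrees) == 0:
        raise ValueError(f"no nodes in group {group!r}")
    curve = EcdfCurve(
        values=degrees.astype(float),
        fractions=np.arange(1, len(degrees) + 1) / len(degrees),
    )
    curve.check_invariants()
    return curve


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """Integer percentage with round-half-up, the convention used in reports."""
    if denominator == 0:
        raise ZeroDivisionError("empty network in percentage computation")
    return int(np.floor(100.0 * numerator / denominator + 0.5))


@dataclass
class NetworkOverlap:
    shared_nodes: int
    pct_a: int
    pct_b: int
    shared_pathways: int | None = None


def network_overlap(
    net_a: MergedNetwork,
    net_b: MergedNetwork,
    homolog_map: pd.DataFrame | None = None,
    pathways_a: PathwayCollection | None = None,
    pathways_b: PathwayCollection | None = None,
) -> NetworkOverlap:
    """Node overlap between two species' networks (connected parts only).

    Nodes of network B are translated into A's namespace through the
    homolog map (columns gene_a, gene_b); with no map, identical ids are
    matched. Percentages are round-half-up integers, the shared pathway
    count is reported when both selected collections are given.
    """
    nodes_a = net_a.nodes
    nodes_b = net_b.nodes
    if homolog_map is not None and len(homolog_map):
        b_to_a = dict(zip(homolog_map["gene_b"], homolog_map["gene_a"]))
        nodes_b = {b_to_a[n] for n in nodes_b if n in b_to_a}
    shared = nodes_a & nodes_b
    shared_pathways = None
    if pathways_a is not None and pathways_b is not None:
        shared_pathways = len(set(pathways_a.members) & set(pathways_b.members))
    return NetworkOverlap(
        shared_nodes=len(shared),
        pct_a=round_half_up_percent(len(shared), len(net_a.nodes)),
        pct_b=round_half_up_percent(len(shared), len(net_b.nodes)),
        shared_pathways=shared_pathways,
    )
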