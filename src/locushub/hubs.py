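"""Hub detection over the multilayer locus graph.

A *hub* is a set of two or more GWAS loci connected either directly or
through non-GWAS intermediary loci within a bounded number of steps.
Bridging paths are simple paths whose endpoints are GWAS loci and whose
interior nodes are all non-GWAS; the graph restricted to edges lying on
such paths decomposes into connected components, and each component with
enough GWAS members is reported as one hub together with the minimal
(shortest per GWAS pair) bridging paths that explain it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .sim import TruthTables

__all__ = [
    "BridgingPath",
    "HubReport",
    "bridging_paths",
    "find_hubs",
    "shared_intermediary_pairs",
    "evaluate_hubs",
]


@dataclass(frozen=True)
class BridgingPath:
    """A simple GWAS-to-GWAS path with per-step layer labels."""

    nodes: tuple[str, ...]
    layers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.layers) != len(self.nodes) - 1:
            raise ValueError("layer sequence must have one entry per step")

    @property
    def length(self) -> int:
        return len(self.layers)


@dataclass
class HubReport:
    hub_id: str
    gwas_members: list[str]
    intermediaries: list[str]
    paths: list[BridgingPath] = field(default_factory=list)
    n_layers_used: int = 0


def _gwas_nodes(graph: nx.MultiGraph) -> set[str]:
    return {n for n, d in graph.nodes(data=True) if d.get("gwas_flag")}


def bridging_paths(
    graph: nx.MultiGraph,
    source: str,
    target: str,
    max_path_len: int,
    gwas: set[str],
    layers: set[str] | None = None,
) -> list[BridgingPath]:
    """All simple paths source->target of <= max_path_len edges whose
    interior nodes are non-GWAS, enumerated per multi-edge so each layer
    combination is a distinct path."""
    out: list[BridgingPath] = []

    def dfs(node: str, visited: tuple[str, ...], layer_seq: tuple[str, ...]) -> None:
        if len(layer_seq) == max_path_len:
            return
        for _, nbr, key, data in graph.edges(node, keys=True, data=True):
            layer = data.get("layer", key)
            if layers is not None and layer not in layers:
                continue
            if nbr == target:
                out.append(BridgingPath(visited + (nbr,), layer_seq + (layer,)))
                continue
            if nbr in visited or nbr in gwas:
                continue
            dfs(nbr, visited + (nbr,), layer_seq + (layer,))

    dfs(source, (source,), ())
    # deterministic order: short paths first, then lexicographic
    out.sort(key=lambda p: (p.length, p.nodes, p.layers))
    return out


def find_hubs(
    graph: nx.MultiGraph,
    max_path_len: int = 3,
    min_gwas: int = 2,
    layers: set[str] | None = None,
) -> list[HubReport]:
    """Detect hubs of GWAS loci bridged within ``max_path_len`` steps.

    The graph is restricted to edges lying on some bridging path; the
    connected components of that restriction containing at least
    ``min_gwas`` GWAS loci are the hubs.  Each hub reports, for every
    GWAS pair it connects, all bridging paths of minimal length for that
    pair.  Hubs are ordered by descending GWAS count then lexicographic
    member ids, so output is independent of input order.
    """
    if max_path_len < 1:
        raise ValueError("max_path_len must be >= 1")
    gwas = _gwas_nodes(graph)

    pair_paths: dict[tuple[str, str], list[BridgingPath]] = {}
    kept_edges: set[tuple[str, str, str]] = set()
    for u, v in itertools.combinations(sorted(gwas), 2):
        paths = bridging_paths(graph, u, v, max_path_len, gwas, layers)
        if not paths:
            continue
        pair_paths[(u, v)] = paths
        for path in paths:
            for a, b, layer in zip(path.nodes, path.nodes[1:], path.layers):
                x, y = sorted((a, b))
                kept_edges.add((x, y, layer))

    restricted = nx.MultiGraph()
    restricted.add_nodes_from(gwas)
    for x, y, layer in kept_edges:
        restricted.add_edge(x, y, key=layer, layer=layer)

    reports = []
    for component in nx.connected_components(restricted):
        members = sorted(component & gwas)
        if len(members) < min_gwas:
            continue
        minimal: list[BridgingPath] = []
        for pair, paths in sorted(pair_paths.items()):
            if pair[0] in component and pair[1] in component:
                best = min(p.length for p in paths)
                minimal.extend(p for p in paths if p.length == best)
        intermediaries = sorted(component - gwas)
        layer_set = {
            layer for x, y, layer in kept_edges if x in component and y in component
        }
        reports.append(
            HubReport(
                hub_id="",
                gwas_members=members,
                intermediaries=intermediaries,
                paths=minimal,
                n_layers_used=len(layer_set),
            )
        )
    reports.sort(key=lambda r: (-len(r.gwas_members), tuple(r.gwas_members)))
    for i, report in enumerate(reports, start=1):
        report.hub_id = f"hub{i}"
    return reports


def shared_intermediary_pairs(graph: nx.MultiGraph) -> list[tuple[str, str, str]]:
    """GWAS pairs sharing a direct non-GWAS neighbour.

    Returns (gwas_u, gwas_v, intermediary) triples with gwas_u < gwas_v
    lexicographically, each unordered pair reported once per shared
    intermediary.  This is the two-step "via GRM5"-style bridge view.
    """
    gwas = _gwas_nodes(graph)
    triples = set()
    for mid in set(graph.nodes) - gwas:
        neighbours = sorted(set(graph.neighbors(mid)) & gwas)
        for u, v in itertools.combinations(neighbours, 2):
            triples.add((u, v, mid))
    return sorted(triples)


def evaluate_hubs(
    reports: list[HubReport], truth: TruthTables
) -> tuple[float, float]:
    """Precision and recall of detected hubs against planted truth.

    A detected hub matches a planted one iff their GWAS member sets are
    equal.  With nothing detected, precision is 1.0 by convention (no
    false claims were made); with nothing planted, recall is 1.0.
    """
    detected = {frozenset(r.gwas_members) for r in reports}
    planted = {frozenset(h) for h in truth.planted_hub_members}
    matched = detected & planted
    precision = len(matched) / len(detected) if detected else 1.0
    recall = len(matched) / len(planted) if planted else 1.0
    return precision, recall
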