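"""Mechanism-subnetwork extraction: union of shortest causal paths from drug
targets to biological processes, plus common upstream controllers.

Given a knowledge assembly, a set of source entities (drug targets) and a
set of sink entities (biological processes or pathologies of interest), the
extraction enumerates *all* tied shortest directed paths for every
(source, sink) pair over the causal edges, and unions them into one graph —
merging paths presupposes keeping ties, so a single arbitrary path would
lose structure.  Edges are unweighted; relation polarity travels as edge
metadata but does not affect path length.

A *common upstream controller* is a node outside the extracted subnetwork
with direct causal out-edges onto on-path nodes of at least two distinct
(source, sink) pairs; such nodes (and their connecting edges) are added for
context without altering any registered path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx

from .bel import (
    BioEntity,
    CausalRelation,
    KnowledgeAssembly,
    to_networkx,
)
from .errors import InvalidQueryError

logger = logging.getLogger(__name__)

__all__ = [
    "PathQuery",
    "MechanismSubnetwork",
    "shortest_path_union",
    "add_upstream_controllers",
    "render_summary",
    "subnetwork_to_networkx",
    "write_graphml",
    "write_edge_table",
]

Pair = tuple[BioEntity, BioEntity]
PathTuple = tuple[BioEntity, ...]


@dataclass(frozen=True)
class PathQuery:
    """Source/sink specification for subnetwork extraction.

    ``causal_only`` restricts traversal to causal relations (increases,
    directly_increases, decreases, directly_decreases, regulates);
    association/correlation edges never form mechanism chains by default.
    ``direction='undirected-fallback'`` retries pairs unreachable in the
    directed graph on the undirected projection and flags them.
    ``all_shortest=False`` keeps a single (deterministic) shortest path per
    pair instead of all ties.
    """

    sources: frozenset[BioEntity]
    sinks: frozenset[BioEntity]
    causal_only: bool = True
    direction: str = "directed"
    all_shortest: bool = True

    def __post_init__(self):
        sources = frozenset(self.sources)
        sinks = frozenset(self.sinks)
        object.__setattr__(self, "sources", sources)
        object.__setattr__(self, "sinks", sinks)
        if not sources or not sinks:
            raise InvalidQueryError("sources and sinks must be non-empty")
        if sources & sinks:
            raise InvalidQueryError("sources and sinks must be disjoint")
        if self.direction not in ("directed", "undirected-fallback"):
            raise InvalidQueryError(
                f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class MechanismSubnetwork:
    """Union of registered shortest paths plus optional controllers.

    ``path_registry`` maps each reachable (source, sink) pair to its tuple
    of shortest paths (node sequences, all of equal length per pair).
    ``controllers`` are context nodes added after extraction; every
    non-controller node lies on at least one registered path.
    """

    nodes: frozenset[BioEntity]
    edges: tuple[CausalRelation, ...]
    path_registry: Mapping[Pair, tuple[PathTuple, ...]]
    controllers: frozenset[BioEntity] = frozenset()
    unreachable_pairs: frozenset[Pair] = frozenset()
    fallback_pairs: frozenset[Pair] = frozenset()
    missing: frozenset[BioEntity] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "path_registry", dict(self.path_registry))
        for (src, sink), paths in self.path_registry.items():
            lengths = {len(p) for p in paths}
            if len(lengths) > 1:
                raise InvalidQueryError(
                    f"paths for {src.as_bel()}->{sink.as_bel()} have "
                    f"unequal lengths")
            for p in paths:
                if p[0] != src or p[-1] != sink:
                    raise InvalidQueryError(
                        "registered path endpoints disagree with its pair")

    def on_path_nodes(self) -> frozenset[BioEntity]:
        return frozenset(
            n for paths in self.path_registry.values()
            for p in paths for n in p
        )

    def pairs_of_node(self) -> dict[BioEntity, set[Pair]]:
        """Which (source, sink) pairs each node participates in."""
        out: dict[BioEntity, set[Pair]] = {}
        for pair, paths in self.path_registry.items():
            for p in paths:
                for n in p:
                    out.setdefault(n, set()).add(pair)
        return out

    def to_assembly(self) -> KnowledgeAssembly:
        """View the subnetwork as a knowledge assembly (for re-querying)."""
        return KnowledgeAssembly(self.nodes, self.edges)


def _edge_lookup(
    assembly: KnowledgeAssembly, causal_only: bool
) -> dict[Pair, list[CausalRelation]]:
    lookup: dict[Pair, list[CausalRelation]] = {}
    for r in assembly.relations:
        if causal_only and not r.is_causal:
            continue
        lookup.setdefault((r.subject, r.object), []).append(r)
    return lookup


def shortest_path_union(
    assembly: KnowledgeAssembly, query: PathQuery
) -> MechanismSubnetwork:
    """Enumerate and union all shortest paths for every (source, sink) pair.

    Sources or sinks absent from the assembly are reported in ``missing``
    (not fatal) unless *all* sources or *all* sinks are missing, which is an
    invalid query.  Pairs with no path are recorded in
    ``unreachable_pairs``; with ``direction='undirected-fallback'`` they are
    retried on the undirected projection and, if then reachable, recorded in
    ``fallback_pairs``.
    """
    g = to_networkx(assembly, causal_only=query.causal_only)
    sources = frozenset(s for s in query.sources if s in g)
    sinks = frozenset(t for t in query.sinks if t in g)
    missing = (query.sources - sources) | (query.sinks - sinks)
    if missing:
        logger.warning("identifiers absent from assembly: %s",
                       sorted(e.as_bel() for e in missing))
    if not sources or not sinks:
        raise InvalidQueryError(
            "all sources or all sinks are missing from the assembly")

    undirected = g.to_undirected(as_view=False)
    registry: dict[Pair, tuple[PathTuple, ...]] = {}
    unreachable: set[Pair] = set()
    fallback: set[Pair] = set()
    for src in sorted(sources):
        for sink in sorted(sinks):
            pair = (src, sink)
            try:
                paths = [tuple(p) for p in nx.all_shortest_paths(g, src, sink)]
            except nx.NetworkXNoPath:
                paths = []
            if not paths and query.direction == "undirected-fallback":
                try:
                    paths = [tuple(p) for p in
                             nx.all_shortest_paths(undirected, src, sink)]
                    fallback.add(pair)
                except nx.NetworkXNoPath:
                    paths = []
            if not paths:
                unreachable.add(pair)
                continue
            paths.sort()
            if not query.all_shortest:
                paths = paths[:1]
            registry[pair] = tuple(paths)

    if not registry:
        logger.warning("no (source, sink) pair is reachable; "
                       "returning an empty subnetwork")
        return MechanismSubnetwork(
            frozenset(), (), {}, frozenset(), frozenset(unreachable),
            frozenset(fallback), frozenset(missing))

    lookup = _edge_lookup(assembly, query.causal_only)
    nodes: set[BioEntity] = set()
    edges: list[CausalRelation] = []
    seen: set[int] = set()

    def take(u: BioEntity, v: BioEntity) -> None:
        for r in lookup.get((u, v), ()):
            if id(r) not in seen:
                seen.add(id(r))
                edges.append(r)

    for pair, paths in registry.items():
        for p in paths:
            nodes.update(p)
            for u, v in zip(p, p[1:]):
                take(u, v)
                if pair in fallback:  # undirected step may use a reverse edge
                    take(v, u)

    return MechanismSubnetwork(
        frozenset(nodes), tuple(edges), registry, frozenset(),
        frozenset(unreachable), frozenset(fallback), frozenset(missing))


def add_upstream_controllers(
    assembly: KnowledgeAssembly,
    subnetwork: MechanismSubnetwork,
    hops: int = 1,
) -> MechanismSubnetwork:
    """Augment the subnetwork with common upstream controllers.

    A node outside the subnetwork qualifies when it has causal out-paths of
    length <= ``hops`` (default 1: direct regulators) onto on-path nodes of
    at least two distinct (source, sink) pairs.  Qualifying nodes, any
    intermediate nodes on their connecting shortest causal paths, and those
    connecting edges are added; nothing is ever removed and registered path
    lengths are unchanged.
    """
    if hops < 1:
        raise InvalidQueryError("hops must be >= 1")
    pair_membership = subnetwork.pairs_of_node()
    on_path = subnetwork.on_path_nodes()
    g = to_networkx(assembly, causal_only=True)
    lookup = _edge_lookup(assembly, causal_only=True)

    # for every outside node: the pairs whose on-path nodes it reaches
    # within `hops` causal steps, and the first hop targets used
    candidate_pairs: dict[BioEntity, set[Pair]] = {}
    candidate_targets: dict[BioEntity, set[BioEntity]] = {}
    for target in sorted(on_path):
        if target not in g:
            continue
        # reverse BFS from the on-path node up to depth `hops`
        lengths = nx.single_source_shortest_path_length(
            g.reverse(copy=False), target, cutoff=hops)
        for u, dist in lengths.items():
            if dist == 0 or u in subnetwork.nodes:
                continue
            candidate_pairs.setdefault(u, set()).update(
                pair_membership.get(target, set()))
            candidate_targets.setdefault(u, set()).add(target)

    controllers = {
        u for u, pairs in candidate_pairs.items() if len(pairs) >= 2
    }
    if not controllers:
        return subnetwork

    new_nodes: set[BioEntity] = set(subnetwork.nodes)
    new_edges: list[CausalRelation] = list(subnetwork.edges)
    seen = {id(r) for r in subnetwork.edges}
    added: set[BioEntity] = set(subnetwork.controllers)

    for u in sorted(controllers):
        added.add(u)
        new_nodes.add(u)
        for target in sorted(candidate_targets[u]):
            for path in nx.all_shortest_paths(g, u, target):
                if len(path) - 1 > hops:
                    continue
                for node in path[1:-1]:
                    if node not in new_nodes:
                        new_nodes.add(node)
                        added.add(node)
                for a, b in zip(path, path[1:]):
                    for r in lookup.get((a, b), ()):
                        if id(r) not in seen:
                            seen.add(id(r))
                            new_edges.append(r)

    return replace(
        subnetwork,
        nodes=frozenset(new_nodes),
        edges=tuple(new_edges),
        controllers=frozenset(added),
    )


# ---------------------------------------------------------------------------
# reporting / export
# ---------------------------------------------------------------------------

def _node_roles(subnetwork: MechanismSubnetwork) -> dict[BioEntity, str]:
    sources = {p[0] for p in subnetwork.path_registry}
    sinks = {p[1] for p in subnetwork.path_registry}
    roles = {}
    for n in subnetwork.nodes:
        if n in subnetwork.controllers:
            roles[n] = "controller"
        elif n in sources:
            roles[n] = "source"
        elif n in sinks:
            roles[n] = "sink"
        else:
            roles[n] = "interior"
    return roles


def _node_depth(subnetwork: MechanismSubnetwork) -> dict[BioEntity, int]:
    """Minimum position of a node along any registered path (controllers:
    -1, placing them upstream in the hierarchy)."""
    depth: dict[BioEntity, int] = {n: -1 for n in subnetwork.controllers}
    for paths in subnetwork.path_registry.values():
        for p in paths:
            for i, n in enumerate(p):
                depth[n] = min(depth.get(n, i), i)
    return depth


def render_summary(subnetwork: MechanismSubnetwork) -> str:
    """Deterministic plain-text report: node table (sources first, interiors
    by distance, sinks, controllers), edge table, and per-pair path
    listing."""
    roles = _node_roles(subnetwork)
    depth = _node_depth(subnetwork)
    role_order = {"source": 0, "interior": 1, "sink": 2, "controller": 3}

    lines = ["# nodes", "entity\trole\tdepth"]
    for n in sorted(subnetwork.nodes,
                    key=lambda n: (role_order[roles[n]],
                                   depth.get(n, 0), n)):
        lines.append(f"{n.as_bel()}\t{roles[n]}\t{depth.get(n, '')}")

    lines += ["", "# edges", "subject\trelation\tobject\tcitation"]
    for r in sorted(subnetwork.edges,
                    key=lambda r: (r.subject, r.object, r.relation)):
        lines.append(
            f"{r.subject.as_bel()}\t{r.relation}\t{r.object.as_bel()}"
            f"\t{r.citation[0]}:{r.citation[1]}")

    lines += ["", "# paths", "source\tsink\tlength\tpath"]
    for (src, sink) in sorted(subnetwork.path_registry):
        for p in subnetwork.path_registry[(src, sink)]:
            chain = " -> ".join(n.as_bel() for n in p)
            lines.append(
                f"{src.as_bel()}\t{sink.as_bel()}\t{len(p) - 1}\t{chain}")
    for (src, sink) in sorted(subnetwork.unreachable_pairs):
        lines.append(f"{src.as_bel()}\t{sink.as_bel()}\tunreachable\t")
    return "\n".join(lines) + "\n"


def subnetwork_to_networkx(subnetwork: MechanismSubnetwork) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    roles = _node_roles(subnetwork)
    for n in sorted(subnetwork.nodes):
        g.add_node(n, role=roles[n])
    for r in subnetwork.edges:
        g.add_edge(r.subject, r.object, relation=r.relation,
                   citation=r.citation)
    return g


def write_graphml(subnetwork: MechanismSubnetwork, path: str | Path) -> None:
    """GraphML export for visualization tools; node ids are BEL strings."""
    g = subnetwork_to_networkx(subnetwork)
    out = nx.MultiDiGraph()
    for n, data in g.nodes(data=True):
        out.add_node(n.as_bel(), function=n.function, namespace=n.namespace,
                     name=n.name, role=data["role"])
    for u, v, data in g.edges(data=True):
        out.add_edge(u.as_bel(), v.as_bel(), relation=data["relation"],
                     citation=f"{data['citation'][0]}:{data['citation'][1]}")
    nx.write_graphml(out, str(path))


def write_edge_table(subnetwork: MechanismSubnetwork, path: str | Path,
                     header: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("subject\trelation\tobject\tcitation_type\tcitation_id\n")
        for r in sorted(subnetwork.edges,
                        key=lambda r: (r.subject, r.object, r.relation)):
            fh.write(
                f"{r.subject.as_bel()}\t{r.relation}\t{r.object.as_bel()}"
                f"\t{r.citation[0]}\t{r.citation[1]}\n")
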