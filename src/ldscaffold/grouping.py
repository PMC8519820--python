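"""Contig graph construction, group formation and linearization.

Valid segment relations are lifted to contigs: one edge per contig pair,
scored by the best supporting segment relation. Connected components of
that graph form contig groups; a group whose subgraph is (after
transitive reduction) a simple path is resolved to a linear contig
order. Marker placements from a genetic map are used as an external
consistency check on the groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from ldscaffold.fingerprint import Segment
from ldscaffold.relations import Relation

__all__ = [
    "ContigGraph",
    "ContigGroup",
    "MarkerPlacement",
    "GroupMarkerReport",
    "build_contig_graph",
    "form_groups",
    "linearize_group",
    "marker_consistency",
    "export_dot",
    "read_markers_tsv",
]

#: groups larger than this are reported complex without attempting
#: transitive reduction
MAX_LINEARIZE_NODES = 30


@dataclass
class ContigGraph:
    """Undirected contig graph with per-edge best score and support."""

    graph: nx.Graph
    intra_contig: list[Relation] = field(default_factory=list)

    @property
    def contigs(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_score(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["score"]


@dataclass
class ContigGroup:
    """A connected component of the contig graph."""

    members: frozenset[str]
    resolution: str  # "linear" or "complex"
    order: list[str] = field(default_factory=list)
    total_bp: int = 0

    def __post_init__(self) -> None:
        if self.resolution == "linear" and set(self.order) != set(self.members):
            raise ValueError("linear order must list every member exactly once")


@dataclass(frozen=True)
class MarkerPlacement:
    marker: str
    contig: str
    position: int
    linkage_group: str
    tier: int = 1


@dataclass
class GroupMarkerReport:
    status: str  # "consistent" | "conflicting" | "unanchored"
    linkage_groups: dict[str, int] = field(default_factory=dict)
    conflicts: list[MarkerPlacement] = field(default_factory=list)
    offending_contigs: list[str] = field(default_factory=list)


def build_contig_graph(
    relations: Iterable[Relation],
    contig_lengths: Mapping[str, int] | None = None,
    valid_only: bool = True,
) -> ContigGraph:
    """Aggregate segment relations into one edge per contig pair.

    Edge score is the max over supporting segment relations; the number
    of shared patterns and the supporting segment pairs are kept as edge
    attributes. Intra-contig relations are stored separately as
    self-consistency evidence and never create edges.
    """
    g = nx.Graph()
    intra: list[Relation] = []
    for rel in relations:
        if valid_only and not rel.valid:
            continue
        if rel.intra_contig:
            intra.append(rel)
            continue
        u, v = rel.segment_a.contig, rel.segment_b.contig
        if g.has_edge(u, v):
            e = g.edges[u, v]
            e["score"] = max(e["score"], rel.score)
            e["n_shared"] += rel.n_shared
            e["support"].append((rel.segment_a.id, rel.segment_b.id, rel.score))
        else:
            g.add_edge(
                u,
                v,
                score=rel.score,
                n_shared=rel.n_shared,
                support=[(rel.segment_a.id, rel.segment_b.id, rel.score)],
            )
    if contig_lengths:
        for node in g.nodes:
            g.nodes[node]["length"] = contig_lengths.get(node, 0)
    return ContigGraph(graph=g, intra_contig=intra)


def form_groups(
    cg: ContigGraph, contig_lengths: Mapping[str, int] | None = None
) -> list[ContigGroup]:
    """Connected components of the contig graph, linearized where possible.

    Isolated contigs never appear (they have no edges by construction).
    Output is deterministic: groups sorted by their smallest member name.
    """
    groups: list[ContigGroup] = []
    for comp in nx.connected_components(cg.graph):
        members = frozenset(comp)
        if len(members) < 2:
            continue
        resolution, order = linearize_group(members, cg)
        bp = sum(contig_lengths.get(c, 0) for c in members) if contig_lengths else 0
        groups.append(ContigGroup(members=members, resolution=resolution, order=order, total_bp=bp))
    groups.sort(key=lambda grp: min(grp.members))
    return groups


def _is_simple_path(g: nx.Graph) -> list[str] | None:
    """Ordered node list if ``g`` is a simple path, else ``None``."""
    if g.number_of_nodes() == 1:
        return list(g.nodes)
    degrees = dict(g.degree())
    ends = [n for n, d in degrees.items() if d == 1]
    if len(ends) != 2 or any(d > 2 for d in degrees.values()):
        return None
    if g.number_of_edges() != g.number_of_nodes() - 1:
        return None  # cycle somewhere
    start = min(ends)
    order = [start]
    prev, cur = None, start
    while len(order) < g.number_of_nodes():
        nxts = [n for n in g.neighbors(cur) if n != prev]
        if len(nxts) != 1:
            return None
        prev, cur = cur, nxts[0]
        order.append(cur)
    return order


def linearize_group(members: Iterable[str], cg: ContigGraph) -> tuple[str, list[str]]:
    """Resolve a group to a linear contig order when unambiguous.

    If the group subgraph is a simple path, the order is returned
    directly (direction from the lexicographically smaller endpoint).
    Otherwise weak transitive edges are removed — an edge (u, w) is
    dropped when a two-step path u-v-w exists whose weaker edge still
    scores higher than (u, w) — and the path test is retried. Anything
    else, or any group above :data:`MAX_LINEARIZE_NODES`, is "complex".
    """
    sub = cg.graph.subgraph(members).copy()
    order = _is_simple_path(sub)
    if order is not None:
        return "linear", order
    if sub.number_of_nodes() > MAX_LINEARIZE_NODES:
        return "complex", []
    # drop weakest transitive edges first so stronger evidence survives
    for u, w, _ in sorted(sub.edges(data="score"), key=lambda e: e[2]):
        if not sub.has_edge(u, w):
            continue
        direct = sub.edges[u, w]["score"]
        for v in set(sub.neighbors(u)) & set(sub.neighbors(w)):
            two_step = min(sub.edges[u, v]["score"], sub.edges[v, w]["score"])
            if two_step > direct:
                sub.remove_edge(u, w)
                break
    order = _is_simple_path(sub)
    if order is not None and nx.is_connected(sub):
        return "linear", order
    return "complex", []


def read_markers_tsv(path: str | Path) -> list[MarkerPlacement]:
    """Read marker placements (marker, contig, pos, linkage group[, tier])."""
    out: list[MarkerPlacement] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tier = int(f[4]) if len(f) > 4 else 1
            out.append(MarkerPlacement(f[0], f[1], int(f[2]), f[3], tier))
    return out


def marker_consistency(
    groups: Sequence[ContigGroup],
    placements: Sequence[MarkerPlacement],
    known_contigs: Iterable[str] | None = None,
) -> dict[int, GroupMarkerReport]:
    """Label each group consistent / conflicting / unanchored.

    A group is conflicting when its contigs carry markers from two or
    more linkage groups; the report lists the conflicting placements and
    the contigs carrying minority-linkage-group markers (candidates for
    the coverage-drop misassembly check). Placements on contigs unknown
    to the assembly are skipped.
    """
    known = set(known_contigs) if known_contigs is not None else None
    by_contig: dict[str, list[MarkerPlacement]] = {}
    for p in placements:
        if known is not None and p.contig not in known:
            continue
        by_contig.setdefault(p.contig, []).append(p)

    reports: dict[int, GroupMarkerReport] = {}
    for gi, group in enumerate(groups):
        marks = [m for c in sorted(group.members) for m in by_contig.get(c, [])]
        if not marks:
            reports[gi] = GroupMarkerReport(status="unanchored")
            continue
        lgs: dict[str, int] = {}
        for m in marks:
            lgs[m.linkage_group] = lgs.get(m.linkage_group, 0) + 1
        if len(lgs) == 1:
            reports[gi] = GroupMarkerReport(status="consistent", linkage_groups=lgs)
            continue
        majority = max(lgs, key=lambda k: (lgs[k], k))
        conflicts = [m for m in marks if m.linkage_group != majority]
        offending = sorted({m.contig for m in conflicts})
        reports[gi] = GroupMarkerReport(
            status="conflicting",
            linkage_groups=lgs,
            conflicts=conflicts,
            offending_contigs=offending,
        )
    return reports


def _dot_escape(name: str) -> str:
    return '"' + name.replace('"', '\\"') + '"'


def export_dot(cg: ContigGraph, members: Iterable[str] | None = None) -> str:
    """Render the contig graph (or one group) as DOT text.

    Nodes carry the contig length as a label annotation when known;
    edges carry the relation score as weight.
    """
    g = cg.graph if members is None else cg.graph.subgraph(members)
    lines = ["graph contigs {"]
    for node in sorted(g.nodes):
        length = g.nodes[node].get("length")
        label = f"{node}\\n{length} bp" if length else node
        lines.append(f"  {_dot_escape(node)} [label={_dot_escape(label)}];")
    for u, v in sorted(tuple(sorted(e)) for e in g.edges):
        lines.append(
            f"  {_dot_escape(u)} -- {_dot_escape(v)} [weight={g.edges[u, v]['score']:.4f}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
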