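"""In-memory knowledge graph with focus-entity statistics and Neo4j export.

Edges store their subject→object direction (relations like *treats* are
directional) but neighborhood statistics and two-hop hypothesis queries
treat the graph as undirected, matching how a researcher reads "directly
related" / "indirectly related".

The bulk-import export writes the two-file CSV layout consumed by
``neo4j-admin import``: a nodes file headed ``name:ID,:LABEL,synonyms,
ids,sources`` and a relationships file headed ``:START_ID,:END_ID,:TYPE,
pmids,sentences,sources``.  List-valued fields are ';'-joined (';' inside
a value is backslash-escaped so a re-import round-trips exactly) with
RFC-4180 quoting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import networkx as nx

from .fusion import CanonicalEdge, CanonicalEntity

__all__ = [
    "GraphError",
    "KnowledgeGraph",
    "StatsReport",
    "TwoHopHypothesis",
    "build",
    "export_neo4j_csv",
    "import_neo4j_csv",
]

#: per_type_counts key for entities whose type vote was unresolved.
UNTYPED_LABEL = "unresolved"


class GraphError(ValueError):
    pass


@dataclass
class StatsReport:
    """Census of a graph around a designated focus entity."""

    focus: str
    total_entities: int
    total_triples: int
    per_type_counts: Dict[str, int]
    direct_triples: int
    indirect_triples: int
    direct_entities: Set[str]
    indirect_entities: Set[str]

    def to_dict(self) -> dict:
        return {
            "focus": self.focus,
            "total_entities": self.total_entities,
            "total_triples": self.total_triples,
            "per_type_counts": dict(sorted(self.per_type_counts.items())),
            "direct_triples": self.direct_triples,
            "indirect_triples": self.indirect_triples,
            "direct_entities": sorted(self.direct_entities),
            "indirect_entities": sorted(self.indirect_entities),
        }


@dataclass(frozen=True)
class TwoHopHypothesis:
    """An endpoint exactly two hops from the focus, with its evidence."""

    intermediate: str
    endpoint: str
    edges: Tuple[CanonicalEdge, ...]


class KnowledgeGraph:
    """Canonical entities plus deduplicated, provenance-carrying edges."""

    def __init__(self) -> None:
        self.nodes: Dict[str, CanonicalEntity] = {}
        self.edges: Dict[Tuple[str, str, str], CanonicalEdge] = {}

    # -- construction ------------------------------------------------------

    def add_entity(self, entity: CanonicalEntity) -> None:
        existing = self.nodes.get(entity.name)
        if existing is None:
            self.nodes[entity.name] = entity
        else:
            existing.synonyms |= entity.synonyms
            existing.ids |= entity.ids
            existing.provenance |= entity.provenance
            if existing.entity_type is None:
                existing.entity_type = entity.entity_type

    def add_edge(self, edge: CanonicalEdge) -> None:
        for endpoint in (edge.subject, edge.object):
            if endpoint not in self.nodes:
                raise GraphError(f"edge endpoint {endpoint!r} is not a known entity")
        existing = self.edges.get(edge.key())
        if existing is None:
            self.edges[edge.key()] = edge
        else:
            existing.pmids |= edge.pmids
            existing.sentences |= edge.sentences
            existing.sources |= edge.sources

    # -- queries -----------------------------------------------------------

    def _undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for s, _r, o in self.edges:
            g.add_edge(s, o)
        return g

    def stats(self, focus: str) -> StatsReport:
        """Direct/indirect partition of triples and entities around focus."""
        if focus not in self.nodes:
            raise GraphError(f"unknown focus entity {focus!r}")
        direct_edges = [e for e in self.edges.values() if focus in (e.subject, e.object)]
        direct_entities = {
            ep for e in direct_edges for ep in (e.subject, e.object) if ep != focus
        }
        indirect_entities = set(self.nodes) - direct_entities - {focus}
        per_type: Dict[str, int] = {}
        for ent in self.nodes.values():
            label = ent.entity_type or UNTYPED_LABEL
            per_type[label] = per_type.get(label, 0) + 1
        return StatsReport(
            focus=focus,
            total_entities=len(self.nodes),
            total_triples=len(self.edges),
            per_type_counts=per_type,
            direct_triples=len(direct_edges),
            indirect_triples=len(self.edges) - len(direct_edges),
            direct_entities=direct_entities,
            indirect_entities=indirect_entities,
        )

    def two_hop(self, focus: str) -> List[TwoHopHypothesis]:
        """Entities at undirected distance exactly 2 from the focus.

        Each hypothesis pairs the intermediate (one-hop) entity with an
        endpoint that is neither the focus nor adjacent to it, carrying
        the two connecting edges as evidence.
        """
        if focus not in self.nodes:
            raise GraphError(f"unknown focus entity {focus!r}")
        g = self._undirected()
        one_hop = set(g.neighbors(focus))
        out: List[TwoHopHypothesis] = []
        for mid in sorted(one_hop):
            for end in sorted(g.neighbors(mid)):
                if end == focus or end in one_hop:
                    continue
                evidence = tuple(
                    e
                    for e in self.edges.values()
                    if {e.subject, e.object} in ({focus, mid}, {mid, end})
                )
                out.append(TwoHopHypothesis(mid, end, evidence))
        return out

    # -- equality (used by round-trip checks) ------------------------------

    def content(self) -> tuple:
        nodes = tuple(
            sorted(
                (
                    n.name,
                    n.entity_type,
                    tuple(sorted(n.synonyms)),
                    tuple(sorted(n.ids)),
                    tuple(sorted({src for _d, src in n.provenance})),
                )
                for n in self.nodes.values()
            )
        )
        edges = tuple(
            sorted(
                (
                    e.subject,
                    e.relation,
                    e.object,
                    tuple(sorted(e.pmids)),
                    tuple(sorted(e.sentences)),
                    tuple(sorted(e.sources)),
                )
                for e in self.edges.values()
            )
        )
        return nodes, edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self.content() == other.content()


def build(
    entities: Sequence[CanonicalEntity], edges: Sequence[CanonicalEdge]
) -> KnowledgeGraph:
    """Assemble a graph, rejecting edges with unknown endpoints."""
    kg = KnowledgeGraph()
    for e in entities:
        kg.add_entity(e)
    dangling = sorted(
        {
            ep
            for edge in edges
            for ep in (edge.subject, edge.object)
            if ep not in kg.nodes
        }
    )
    if dangling:
        raise GraphError(f"edges reference unknown entities: {dangling}")
    for edge in edges:
        kg.add_edge(edge)
    return kg


# --------------------------------------------------------------------------
# Neo4j bulk-import CSV

NODES_HEADER = ["name:ID", ":LABEL", "synonyms", "ids", "sources"]
RELS_HEADER = [":START_ID", ":END_ID", ":TYPE", "pmids", "sentences", "sources"]


def _join_list(values: Set[str]) -> str:
    return ";".join(v.replace("\\", "\\\\").replace(";", "\\;") for v in sorted(values))


def _split_list(value: str) -> Set[str]:
    items: List[str] = []
    buf: List[str] = []
    i = 0
    while i < len(value):
        c = value[i]
        if c == "\\" and i + 1 < len(value):
            buf.append(value[i + 1])
            i += 2
        elif c == ";":
            items.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(c)
            i += 1
    if buf or value:
        items.append("".join(buf))
    return {x for x in items if x != ""}


def export_neo4j_csv(graph: KnowledgeGraph, directory: str | Path) -> Tuple[Path, Path]:
    """Write ``nodes.csv`` and ``relationships.csv`` for neo4j-admin import."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes_path = directory / "nodes.csv"
    rels_path = directory / "relationships.csv"
    with nodes_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(NODES_HEADER)
        for name in sorted(graph.nodes):
            n = graph.nodes[name]
            w.writerow(
                [
                    n.name,
                    n.entity_type or UNTYPED_LABEL,
                    _join_list(n.synonyms),
                    _join_list(n.ids),
                    _join_list({src for _d, src in n.provenance}),
                ]
            )
    with rels_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RELS_HEADER)
        for key in sorted(graph.edges):
            e = graph.edges[key]
            w.writerow(
                [
                    e.subject,
                    e.object,
                    e.relation,
                    _join_list(e.pmids),
                    _join_list(e.sentences),
                    _join_list(e.sources),
                ]
            )
    return nodes_path, rels_path


def import_neo4j_csv(directory: str | Path) -> KnowledgeGraph:
    """Re-parse an exported directory back into a graph (round-trip check)."""
    directory = Path(directory)
    kg = KnowledgeGraph()
    with (directory / "nodes.csv").open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != NODES_HEADER:
            raise GraphError(f"unexpected nodes header {header}")
        for name, label, synonyms, ids, sources in reader:
            kg.add_entity(
                CanonicalEntity(
                    name=name,
                    synonyms=_split_list(synonyms),
                    entity_type=None if label == UNTYPED_LABEL else label,
                    ids=_split_list(ids),
                    provenance={("", src) for src in _split_list(sources)},
                )
            )
    with (directory / "relationships.csv").open(
        "r", encoding="utf-8", newline=""
    ) as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != RELS_HEADER:
            raise GraphError(f"unexpected relationships header {header}")
        for start, end, rel, pmids, sentences, sources in reader:
            kg.add_edge(
                CanonicalEdge(
                    subject=start,
                    relation=rel,
                    object=end,
                    pmids=_split_list(pmids),
                    sentences=_split_list(sentences),
                    sources=_split_list(sources),
                )
            )
    return kg
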