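"""Knowledge-graph construction, statistics, two-hop queries and export."""

from __future__ import annotations

import random

import pytest

from litkg.fusion import CanonicalEdge, CanonicalEntity, canonicalize_and_merge
from litkg.graph import (
    GraphError,
    build,
    export_neo4j_csv,
    import_neo4j_csv,
)


def ent(name: str, typ: str = "disease", **kw) -> CanonicalEntity:
    return CanonicalEntity(name=name, entity_type=typ, **kw)


def edge(s: str, o: str, rel: str = "associated_with", **kw) -> CanonicalEdge:
    defaults = dict(pmids={"P1"}, sentences={f"{s} and {o}"}, sources={"literature"})
    defaults.update(kw)
    return CanonicalEdge(subject=s, relation=rel, object=o, **defaults)


def test_build_small_graph():
    kg = build([ent("HCC"), ent("Sorafenib", "drug")], [edge("Sorafenib", "HCC", "treats")])
    assert len(kg.nodes) == 2 and len(kg.edges) == 1


def test_build_rejects_dangling_edge():
    with pytest.raises(GraphError, match="unknown entities"):
        build([ent("HCC")], [edge("Sorafenib", "HCC")])


def test_duplicate_edge_keys_merge_provenance():
    kg = build(
        [ent("a"), ent("b")],
        [
            edge("a", "b", pmids={"P1"}, sources={"literature"}),
            edge("a", "b", pmids={"P2"}, sources={"semmeddb"}),
        ],
    )
    (e,) = kg.edges.values()
    assert e.pmids == {"P1", "P2"} and e.sources == {"literature", "semmeddb"}


def test_stats_star_graph():
    kg = build(
        [ent("hub"), ent("a"), ent("b"), ent("c")],
        [edge("hub", "a"), edge("hub", "b"), edge("hub", "c")],
    )
    report = kg.stats("hub")
    assert report.direct_triples == 3 and report.indirect_triples == 0
    assert report.direct_entities == {"a", "b", "c"}
    assert report.indirect_entities == set()


def test_stats_path_graph_partition():
    kg = build(
        [ent("focus"), ent("b"), ent("c"), ent("d")],
        [edge("focus", "b"), edge("b", "c"), edge("c", "d")],
    )
    report = kg.stats("focus")
    assert report.direct_triples == 1 and report.indirect_triples == 2
    assert report.direct_entities == {"b"}
    assert report.indirect_entities == {"c", "d"}
    assert report.direct_triples + report.indirect_triples == report.total_triples
    assert sum(report.per_type_counts.values()) == report.total_entities


def test_stats_edgeless_graph():
    kg = build([ent("only")], [])
    report = kg.stats("only")
    assert report.total_entities == 1 and report.total_triples == 0
    assert report.direct_triples == 0 and report.indirect_entities == set()


def test_stats_unknown_focus():
    kg = build([ent("a")], [])
    with pytest.raises(GraphError, match="unknown focus"):
        kg.stats("nope")


def test_two_hop_glucagon_hypothesis():
    kg = build(
        [ent("HCC"), ent("Hepatitis A"), ent("Glucagon", "drug")],
        [edge("HCC", "Hepatitis A"), edge("Glucagon", "Hepatitis A")],
    )
    hops = kg.two_hop("HCC")
    assert {(h.intermediate, h.endpoint) for h in hops} == {("Hepatitis A", "Glucagon")}
    (h,) = hops
    assert {frozenset((e.subject, e.object)) for e in h.edges} == {
        frozenset(("HCC", "Hepatitis A")),
        frozenset(("Glucagon", "Hepatitis A")),
    }


def test_two_hop_excludes_adjacent_nodes():
    kg = build(
        [ent("a"), ent("b"), ent("c")],
        [edge("a", "b"), edge("b", "c"), edge("a", "c")],
    )
    assert kg.two_hop("a") == []


def test_two_hop_isolated_focus():
    kg = build([ent("a"), ent("b"), ent("c")], [edge("b", "c")])
    assert kg.two_hop("a") == []


def _random_graph(rng: random.Random):
    names = [f"entity {i}" for i in range(rng.randint(2, 8))]
    types = ["disease", "drug", "gene", None]
    entities = [
        CanonicalEntity(
            name=n,
            entity_type=rng.choice(types),
            synonyms={n.upper(), f"{n}, alt"} if rng.random() < 0.7 else set(),
            ids={f"C{rng.randint(1, 99)}"},
            provenance={("P1", rng.choice(["literature", "semmeddb"]))},
        )
        for n in names
    ]
    edges = []
    for _ in range(rng.randint(0, 12)):
        s, o = rng.sample(names, 2)
        edges.append(
            CanonicalEdge(
                subject=s,
                relation=rng.choice(["treats", "causes"]),
                object=o,
                pmids={f"P{rng.randint(1, 5)}"},
                sentences={f"{s}; then {o} was seen, truly"},
                sources={rng.choice(["literature", "uptodate"])},
            )
        )
    return entities, edges


def test_stats_partition_identities_on_random_graphs():
    rng = random.Random(5)
    for _ in range(30):
        entities, edges = _random_graph(rng)
        kg = build(entities, edges)
        focus = rng.choice(list(kg.nodes))
        report = kg.stats(focus)
        assert report.direct_triples + report.indirect_triples == report.total_triples
        assert not report.direct_entities & report.indirect_entities
        assert focus not in report.direct_entities | report.indirect_entities
        assert sum(report.per_type_counts.values()) == report.total_entities
        one_hop = report.direct_entities
        for h in kg.two_hop(focus):
            assert h.endpoint not in one_hop and h.endpoint != focus


def test_export_single_triple_counts(tmp_path):
    kg = build([ent("a"), ent("b")], [edge("a", "b")])
    nodes_path, rels_path = export_neo4j_csv(kg, tmp_path)
    assert len(nodes_path.read_text().splitlines()) == 3  # header + 2 nodes
    assert len(rels_path.read_text().splitlines()) == 2  # header + 1 edge


def test_export_import_round_trip_random(tmp_path):
    rng = random.Random(11)
    for trial in range(20):
        entities, edges = _random_graph(rng)
        kg = build(entities, edges)
        out = tmp_path / f"g{trial}"
        export_neo4j_csv(kg, out)
        assert import_neo4j_csv(out) == kg


def test_export_quotes_commas_and_semicolons(tmp_path):
    tricky = CanonicalEntity(
        name="entity, with comma",
        entity_type="drug",
        synonyms={'syn "quoted"', "semi;colon", "plain"},
        ids={"C1"},
        provenance={("P1", "literature")},
    )
    other = ent("partner")
    e = edge("entity, with comma", "partner", sentences={"a, b; c\nd"})
    kg = build([tricky, other], [e])
    out = tmp_path / "tricky"
    export_neo4j_csv(kg, out)
    assert import_neo4j_csv(out) == kg


def test_fused_bundle_graph_round_trip(tmp_path, gold_bundle):
    result = canonicalize_and_merge(gold_bundle.gold_triples)
    kg = build(result.entities, result.edges)
    export_neo4j_csv(kg, tmp_path / "kg")
    assert import_neo4j_csv(tmp_path / "kg") == kg
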