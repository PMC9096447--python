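import datetime

import networkx as nx
import numpy as np
import pytest

import biotagme as bt
from biotagme import corpus
from biotagme.errors import LookupFailure, ValidationError
from biotagme.graph import Edge, EdgeType, KnowledgeGraph, Node, NodeType, edge_provenance
from biotagme.scoring import ScoredPair


def scored(i, j, s=0.5, r=0.8):
    return ScoredPair(entity_i=i, entity_j=j, s=s, r=r, biotg=s * r)


def annotation(doc, page):
    from biotagme.annotator import Annotation

    return Annotation(doc_id=doc, anchor_text="x", page_id=page, commonness=1, coherence=0, rho=0.5)


@pytest.fixture()
def small_graph():
    """Chain A-B-C plus isolated D, with all three edge types on A-B."""
    g = KnowledgeGraph()
    for nid, name, typ in [(0, "A", NodeType.GENE), (1, "B", NodeType.PROTEIN),
                           (2, "C", NodeType.DISEASE), (3, "D", NodeType.OTHER)]:
        g.add_node(Node(node_id=nid, name=name, type=typ))
    g.add_edge(Edge(0, 1, EdgeType.BIOTAGME, biotagme_score=0.9, doc_ids=frozenset({"d1"})))
    g.add_edge(Edge(0, 1, EdgeType.STRING, string_score=0.7))
    g.add_edge(Edge(0, 1, EdgeType.LITERATURE, literature_flag=1, origins=frozenset({"DisGeNET"})))
    g.add_edge(Edge(1, 2, EdgeType.BIOTAGME, biotagme_score=0.4, doc_ids=frozenset({"d2"})))
    return g


class TestEdgeInvariants:
    def test_biotagme_edge_requires_score(self):
        with pytest.raises(ValidationError):
            Edge(0, 1, EdgeType.BIOTAGME)

    def test_string_edge_requires_score(self):
        with pytest.raises(ValidationError):
            Edge(0, 1, EdgeType.STRING)

    def test_no_self_loops(self):
        with pytest.raises(ValidationError):
            Edge(1, 1, EdgeType.LITERATURE)


class TestBuildGraph:
    def test_predicted_pair_also_in_literature(self):
        preds = [scored(10, 20)]
        lit = [corpus.ReferenceEdge("10", "20", origin="DisGeNET")]
        anns = [annotation("d1", 10), annotation("d1", 20)]
        g = bt.build_graph(preds, lit, [], corpus.SynonymTable(), anns)
        assert g.n_nodes == 2
        assert {e.edge_type for e in g.edges.values()} == {EdgeType.BIOTAGME, EdgeType.LITERATURE}
        biotg = next(e for e in g.edges.values() if e.edge_type is EdgeType.BIOTAGME)
        assert biotg.doc_ids == {"d1"}

    def test_empty_inputs_give_empty_graph(self):
        g = bt.build_graph([], [], [], corpus.SynonymTable(), [])
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_pair_can_carry_all_three_edge_types(self):
        preds = [scored(10, 20)]
        lit = [corpus.ReferenceEdge("10", "20", origin="DrugBank")]
        string = [corpus.ReferenceEdge("10", "20", origin="STRING", score=0.9)]
        g = bt.build_graph(preds, lit, string, corpus.SynonymTable(), [annotation("d", 10), annotation("d", 20)])
        assert g.n_nodes == 2
        assert g.n_edges == 3
        assert {e.edge_type for e in g.edges.values()} == set(EdgeType)

    def test_reference_only_node_typed_from_origin(self):
        lit = [corpus.ReferenceEdge("mir-21", "PTEN", origin="miRTarBase")]
        g = bt.build_graph([], lit, [], corpus.SynonymTable(), [])
        types = {g.nodes[n].name: g.nodes[n].type for n in g.nodes}
        assert types["mir-21"] is NodeType.MIRNA

    def test_aliases_unify_reference_and_predicted_names(self, synth_config, synth_wiki, synth_corpus, synth_annotations):
        docs, truth = synth_corpus
        literature, string_edges, synonyms = bt.generate_references(synth_wiki, truth, synth_config)
        literature = corpus.harmonize_names(literature, synonyms)
        string_edges = corpus.harmonize_names(string_edges, synonyms)
        preds = bt.predict(synth_annotations, synth_wiki)
        g = bt.build_graph(preds, literature, string_edges, synonyms, synth_annotations, wiki=synth_wiki)
        # every reference name resolves to an annotated entity node: no
        # name-only duplicates survive harmonization
        assert g.n_nodes == len({p for pr in preds for p in pr.pair})


class TestEchoNetwork:
    def test_n_below_ten_rejected(self, small_graph):
        with pytest.raises(ValidationError):
            bt.echo_network(small_graph, "A", n=9)

    def test_n_above_two_hundred_rejected(self, small_graph):
        with pytest.raises(ValidationError):
            bt.echo_network(small_graph, "B", n=201)

    def test_fewer_neighbors_than_n(self, small_graph):
        sub = bt.echo_network(small_graph, "B", n=10)
        assert sub.n_nodes == 3  # seed + its 2 neighbors

    def test_unknown_name_raises(self, small_graph):
        with pytest.raises(LookupFailure):
            bt.echo_network(small_graph, "nope", n=10)

    def test_neighbor_type_restriction_and_ranking(self):
        g = KnowledgeGraph()
        g.add_node(Node(0, "seed", type=NodeType.GENE))
        for nid, score, typ in [(1, 0.9, NodeType.DISEASE), (2, 0.5, NodeType.DISEASE), (3, 0.1, NodeType.DRUG)]:
            g.add_node(Node(nid, f"n{nid}", type=typ))
            g.add_edge(Edge(0, nid, EdgeType.BIOTAGME, biotagme_score=score))
        sub = bt.echo_network(g, "seed", neighbor_types=[NodeType.DISEASE], n=10)
        assert set(sub.nodes) == {0, 1, 2}

    def test_result_bounded_by_n_plus_one(self, synth_wiki, synth_annotations):
        preds = bt.predict(synth_annotations, synth_wiki)
        g = bt.build_graph(preds, [], [], corpus.SynonymTable(), synth_annotations, wiki=synth_wiki)
        name = g.nodes[0].name
        sub = bt.echo_network(g, name, n=10)
        assert sub.n_nodes <= 11

    def test_subgraph_keeps_edges_between_included_nodes(self, small_graph):
        sub = bt.echo_network(small_graph, "B", n=10)
        assert len(sub.edges_between(0, 1)) == 3


class TestShortestPath:
    def test_src_equals_dst(self, small_graph):
        path = bt.shortest_path(small_graph, "A", dst_name="A")
        assert len(path) == 1 and path[0][1] is None

    def test_chain_path(self, small_graph):
        path = bt.shortest_path(small_graph, "A", dst_name="C")
        assert [node.name for node, _ in path] == ["A", "B", "C"]
        assert path[0][1] is None and path[1][1] is not None

    def test_disconnected_gives_empty(self, small_graph):
        assert bt.shortest_path(small_graph, "A", dst_name="D") == []

    def test_agrees_with_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for trial in range(15):
            n = int(rng.integers(10, 101))
            gnx = nx.gnp_random_graph(n, 0.06, seed=int(rng.integers(0, 2**31)))
            g = KnowledgeGraph()
            for node in gnx.nodes:
                g.add_node(Node(node, f"n{node}"))
            for u, v in gnx.edges:
                a, b = min(u, v), max(u, v)
                g.add_edge(Edge(a, b, EdgeType.BIOTAGME, biotagme_score=1.0))
            src, dst = (int(x) for x in rng.choice(n, size=2, replace=False))
            path = bt.shortest_path(g, f"n{src}", dst_name=f"n{dst}")
            if nx.has_path(gnx, src, dst):
                assert len(path) - 1 == nx.shortest_path_length(gnx, src, dst)
            else:
                assert path == []

    def test_lexicographically_smallest_among_ties(self):
        # two 2-hop paths A-B-D and A-C-D: the B route (smaller id) wins
        g = KnowledgeGraph()
        for nid, name in enumerate("ABCD"):
            g.add_node(Node(nid, name))
        for u, v in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            g.add_edge(Edge(u, v, EdgeType.BIOTAGME, biotagme_score=1.0))
        path = bt.shortest_path(g, "A", dst_name="D")
        assert [node.name for node, _ in path] == ["A", "B", "D"]


class TestProvenance:
    def test_literature_backed_pair_has_evidence_bit(self, small_graph):
        edge = small_graph.edges[(0, 1, EdgeType.BIOTAGME)]
        record = edge_provenance(small_graph, edge)
        assert record["literature_evidence"] == 1
        assert record["biotagme_score"] == 0.9
        assert record["string_score"] == 0.7
        assert record["doc_ids"] == ["d1"]

    def test_purely_predicted_pair(self, small_graph):
        edge = small_graph.edges[(1, 2, EdgeType.BIOTAGME)]
        record = edge_provenance(small_graph, edge)
        assert record["literature_evidence"] == 0
        assert record["string_score"] is None
        assert record["doc_ids"] == ["d2"]

    def test_string_only_pair(self):
        g = KnowledgeGraph()
        g.add_node(Node(0, "A"))
        g.add_node(Node(1, "B"))
        g.add_edge(Edge(0, 1, EdgeType.STRING, string_score=0.6))
        record = edge_provenance(g, g.edges[(0, 1, EdgeType.STRING)])
        assert record["biotagme_score"] is None
        assert record["string_score"] == 0.6


class TestUpdateGraph:
    @pytest.fixture()
    def update_setup(self, synth_config, synth_wiki, synth_corpus):
        docs, _truth = synth_corpus
        cut = datetime.date(2020, 1, 1)
        base_docs = [d for d in docs if d.date < cut]
        delta = [d for d in docs if d.date >= cut]
        anns = bt.annotate_corpus(base_docs, synth_wiki)
        preds = bt.predict(anns, synth_wiki)
        base = bt.build_graph(preds, [], [], corpus.SynonymTable(), anns, wiki=synth_wiki)
        return base, delta, cut, synth_wiki

    def test_empty_delta_returns_base(self, update_setup):
        base, _delta, cut, wiki = update_setup
        out = bt.update_graph(base, [], cut, datetime.date(2021, 1, 1), wiki, bt.UpdateConfig())
        assert out is base

    def test_idempotent_merge(self, update_setup):
        base, delta, cut, wiki = update_setup
        maxdate = datetime.date(2021, 1, 1)
        once = bt.update_graph(base, delta, cut, maxdate, wiki, bt.UpdateConfig())
        twice = bt.update_graph(once, delta, cut, maxdate, wiki, bt.UpdateConfig())
        assert once == twice

    def test_new_pair_gets_exactly_one_new_edge(self, clean_setup):
        _config, wiki, _docs, _truth = clean_setup
        anns = [annotation("d1", 1), annotation("d1", 3)]
        preds = bt.predict(anns, wiki)
        base = bt.build_graph(preds, [], [], corpus.SynonymTable(), anns, wiki=wiki)
        delta_doc = corpus.Document("d9", title="", abstract="bfg2 and factor 1", date=datetime.date(2020, 6, 1))
        out = bt.update_graph(
            base, [delta_doc], datetime.date(2020, 1, 1), datetime.date(2020, 12, 31),
            wiki, bt.UpdateConfig(annotation=bt.AnnotationParams(rho_threshold=0.0)),
        )
        new_edges = [e for key, e in out.edges.items() if key not in base.edges]
        assert len(new_edges) == 1
        assert new_edges[0].edge_type is EdgeType.BIOTAGME

    def test_doc_ids_unioned_and_scores_recomputed(self, update_setup):
        base, delta, cut, wiki = update_setup
        out = bt.update_graph(base, delta, cut, datetime.date(2021, 1, 1), wiki, bt.UpdateConfig())
        for key, edge in base.edges.items():
            if key in out.edges and edge.edge_type is EdgeType.BIOTAGME:
                assert edge.doc_ids <= out.edges[key].doc_ids

    def test_edge_uniqueness_after_updates(self, update_setup):
        base, delta, cut, wiki = update_setup
        out = bt.update_graph(base, delta, cut, datetime.date(2021, 1, 1), wiki, bt.UpdateConfig())
        seen = set()
        for u, v, t in out.edges:
            assert (u, v, t) not in seen
            seen.add((u, v, t))
        assert all(u < v for u, v, _ in out.edges)

    def test_reversed_date_range_rejected(self, update_setup):
        base, _delta, cut, wiki = update_setup
        with pytest.raises(ValidationError):
            bt.update_graph(base, [], cut, cut - datetime.timedelta(days=1), wiki)


class TestGraphRoundTrip:
    def test_write_then_read_is_isomorphic(self, small_graph, tmp_path):
        corpus.write_graph(small_graph, tmp_path)
        back = corpus.read_graph(tmp_path)
        assert back == small_graph

    def test_empty_graph_writes_header_only_tables(self, tmp_path):
        corpus.write_graph(KnowledgeGraph(), tmp_path)
        assert (tmp_path / "nodes.csv").read_text().strip() == "node_id,name,type,wiki_page_id"
        assert corpus.read_graph(tmp_path) == KnowledgeGraph()

    def test_three_edge_types_three_rows(self, small_graph, tmp_path):
        corpus.write_graph(small_graph, tmp_path)
        rows = (tmp_path / "edges.csv").read_text().strip().splitlines()[1:]
        ab_rows = [r for r in rows if r.startswith("0,1,")]
        assert len(ab_rows) == 3
        assert len({r.split(",")[2] for r in ab_rows}) == 3

    def test_graphml_written_and_parseable(self, small_graph, tmp_path):
        corpus.write_graph(small_graph, tmp_path)
        gml = nx.read_graphml(tmp_path / "graph.graphml")
        assert gml.number_of_nodes() == small_graph.n_nodes
        assert gml.number_of_edges() == small_graph.n_edges
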