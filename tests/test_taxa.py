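import warnings

import pytest
from hypothesis import given, settings, strategies as st

from genoclust import (
    RelationGraph,
    filter_different_names_connected,
    filter_larger_component,
    filter_remove_isolated,
    filter_same_names_not_connected,
    parse_binomial,
)
from genoclust.graph import components


class TestParseBinomial:
    def test_binomial_with_type_strain_marker(self):
        t = parse_binomial("Rhizobium gallicum SEMIA 4085^T^")
        assert t.genus == "Rhizobium"
        assert t.epithet == "gallicum"
        assert t.strain == "SEMIA 4085"
        assert t.species_key == "rhizobium gallicum"
        assert t.qualifier == "none"

    def test_quoted_name_is_flagged_but_keyed(self):
        t = parse_binomial('"Aminobacter aminovorans" KCTC 2477^T^')
        assert t.species_key == "aminobacter aminovorans"
        assert t.qualifier == "candidatus-or-quoted"

    def test_sp_placeholder_has_no_species_key(self):
        t = parse_binomial("Aminobacter sp. SR38")
        assert t.species_key is None
        assert t.qualifier == "sp-placeholder"
        assert t.genus == "Aminobacter"
        assert t.strain == "SR38"

    def test_subspecies_share_a_species_key(self):
        a = parse_binomial("Bartonella vinsonii subsp. arupensis OK-94-513^T^")
        b = parse_binomial("Bartonella vinsonii subsp. berkhoffii ATCC 51672^T^")
        assert a.species_key == b.species_key == "bartonella vinsonii"

    def test_single_token_label(self):
        t = parse_binomial("GCF_000421945.1")
        assert t.species_key is None

    @given(st.text(max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_total_on_arbitrary_strings(self, s):
        t = parse_binomial(s)
        assert t.raw == s
        assert isinstance(t.strain, str)


def _graph(edges, extra_nodes=()):
    nodes = sorted({v for e in edges for v in e} | set(extra_nodes))
    return RelationGraph.from_edges(nodes, edges)


class TestRemoveIsolated:
    def test_triangle_plus_isolated(self):
        g = _graph([("a", "b"), ("a", "c"), ("b", "c")], extra_nodes=["d"])
        out = filter_remove_isolated(g)
        assert set(out.nodes) == {"a", "b", "c"}
        assert out.edges == g.edges

    def test_edgeless_graph_empties(self):
        g = _graph([], extra_nodes=list("abc"))
        assert filter_remove_isolated(g).n_nodes == 0

    def test_keeps_exactly_positive_degree_nodes(self, rng):
        from oracles import random_graph

        for _ in range(20):
            nodes, edges = random_graph(rng, max_nodes=15)
            g = RelationGraph.from_edges(nodes, edges)
            adj = g.adjacency()
            out = filter_remove_isolated(g)
            assert set(out.nodes) == {v for v in nodes if adj[v]}


class TestLargerComponent:
    def test_only_keeps_biggest(self):
        g = _graph([("a", "b"), ("b", "c")], extra_nodes=["d"])
        out = filter_larger_component(g, "only")
        assert set(out.nodes) == {"a", "b", "c"}

    def test_remove_drops_biggest(self):
        g = _graph([("a", "b"), ("b", "c")], extra_nodes=["d"])
        out = filter_larger_component(g, "remove")
        assert set(out.nodes) == {"d"}

    def test_tie_is_deterministic_and_warns(self):
        g = _graph([("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")])
        with pytest.warns(UserWarning, match="tie"):
            out = filter_larger_component(g, "only")
        assert set(out.nodes) == {"a", "b", "c"}
        with pytest.warns(UserWarning):
            out2 = filter_larger_component(g, "remove")
        assert set(out2.nodes) == {"x", "y", "z"}

    def test_empty_graph_passthrough(self):
        g = RelationGraph((), frozenset())
        assert filter_larger_component(g, "only").n_nodes == 0


class TestDifferentNamesConnected:
    def test_two_named_species_retained(self):
        g = _graph([("Rhizobium fabae CCBAU 33202^T^", "Rhizobium pisi DSM 30132^T^")])
        out = filter_different_names_connected(g)
        assert out.n_nodes == 2

    def test_single_name_component_dropped(self):
        g = _graph(
            [
                ("Ensifer meliloti A", "Ensifer meliloti B"),
                ("Ensifer meliloti B", "Ensifer meliloti C"),
            ]
        )
        assert filter_different_names_connected(g).n_nodes == 0

    def test_sp_placeholder_rides_along_but_never_triggers(self):
        # placeholder in a two-name component is retained
        g = _graph(
            [
                ("Aminobacter ciceronei DSM 17455^T^", "Chelatobacter heintzii KCTC 2477^T^"),
                ("Chelatobacter heintzii KCTC 2477^T^", "Aminobacter sp. SR38"),
            ]
        )
        out = filter_different_names_connected(g)
        assert "Aminobacter sp. SR38" in out.nodes
        # placeholder plus one name is not two names
        g2 = _graph([("Aminobacter sp. SR38", "Aminobacter ciceronei DSM 17455^T^")])
        assert filter_different_names_connected(g2).n_nodes == 0

    def test_matches_per_component_recount(self, rng):
        names = [
            "Genus alpha S1", "Genus alpha S2", "Genus beta S1",
            "Genus gamma S1", "Genus sp. S9", "Other delta S1",
            "Other epsilon S1", "Other sp. S2",
        ]
        from oracles import random_graph

        for _ in range(25):
            nodes, edges = random_graph(rng, max_nodes=8, labels=names)
            g = RelationGraph.from_edges(nodes, edges)
            out = filter_different_names_connected(g)
            expected = set()
            for comp in components(g):
                keys = {
                    parse_binomial(v).species_key
                    for v in comp
                    if parse_binomial(v).species_key
                }
                if len(keys) >= 2:
                    expected |= set(comp)
            assert set(out.nodes) == expected


class TestSameNamesNotConnected:
    def test_split_species_retained(self):
        g = _graph(
            [
                ("Xanthobacter autotrophicus DSM 432^T^", "Xanthobacter tagetidis X"),
            ],
            extra_nodes=['"Xanthobacter autotrophicus" Py2'],
        )
        out = filter_same_names_not_connected(g)
        assert set(out.nodes) == {
            "Xanthobacter autotrophicus DSM 432^T^",
            '"Xanthobacter autotrophicus" Py2',
        }

    def test_connected_same_names_dropped(self):
        g = _graph([("Aminobacter aminovorans DSM 7048^T^",
                     "Aminobacter aminovorans NCTC 10684^T^")])
        assert filter_same_names_not_connected(g).n_nodes == 0

    def test_matches_split_species_scan(self, rng):
        names = [
            "Genus alpha S1", "Genus alpha S2", "Genus alpha S3",
            "Genus beta S1", "Genus beta S2", "Genus sp. S9",
            "Other gamma S1", "Other gamma S2",
        ]
        from oracles import random_graph

        for _ in range(25):
            nodes, edges = random_graph(rng, max_nodes=8, labels=names)
            g = RelationGraph.from_edges(nodes, edges)
            comp_of = {}
            for ci, comp in enumerate(components(g)):
                for v in comp:
                    comp_of[v] = ci
            by_key = {}
            for v in nodes:
                k = parse_binomial(v).species_key
                if k:
                    by_key.setdefault(k, []).append(v)
            expected = set()
            for k, vs in by_key.items():
                if len({comp_of[v] for v in vs}) >= 2:
                    expected |= set(vs)
            assert set(filter_same_names_not_connected(g).nodes) == expected


class TestFilterProperties:
    @pytest.mark.parametrize(
        "filt",
        [
            filter_remove_isolated,
            lambda g: filter_larger_component(g, "only"),
            filter_different_names_connected,
            filter_same_names_not_connected,
        ],
        ids=["remove-isolated", "only-larger", "different-names", "same-names"],
    )
    def test_idempotent_and_never_adds(self, filt, rng):
        from oracles import random_graph

        names = ["Genus alpha S1", "Genus alpha S2", "Genus beta S1",
                 "Genus beta S2", "Other gamma S1", "Other gamma S2",
                 "Genus sp. S7", "Other delta S1"]
        for _ in range(15):
            nodes, edges = random_graph(rng, max_nodes=8, labels=names)
            g = RelationGraph.from_edges(nodes, edges)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                once = filt(g)
                twice = filt(once)
            assert set(once.nodes) <= set(g.nodes)
            assert once.edges <= g.edges
            assert set(twice.nodes) == set(once.nodes)
            assert twice.edges == once.edges

    def test_remove_larger_never_adds_but_is_not_idempotent(self, rng):
        # removing "the" largest component exposes a new largest, so a second
        # application keeps shrinking the graph; only monotonicity holds
        from oracles import random_graph

        for _ in range(15):
            nodes, edges = random_graph(rng, max_nodes=10)
            g = RelationGraph.from_edges(nodes, edges)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                once = filter_larger_component(g, "remove")
                twice = filter_larger_component(once, "remove")
            assert set(once.nodes) <= set(g.nodes)
            assert once.edges <= g.edges
            assert set(twice.nodes) <= set(once.nodes)
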