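"""Reaction graphs, metabolic maps, module views and exports."""

import networkx as nx
import numpy as np
import pytest

from commet.decompose import Module
from commet.model_core import MetabolicModel, Metabolite, Reaction
from commet.network import (UBIQUITOUS_METABOLITES, build_metabolic_map,
                            build_reaction_graph, expand_first_neighbors,
                            export_graph, single_module_view)


@pytest.fixture
def toy_model():
    """Five reactions: r1/r2 share pyruvate, r2/r3 share only ATP,
    r4 consumes a metabolite produced by r1, r5 is isolated."""
    mets = [
        Metabolite("m_pyr", "pyruvate", "c"),
        Metabolite("m_atp", "ATP", "c"),
        Metabolite("m_acc", "acetyl-CoA", "m"),
        Metabolite("m_h2o", "H2O", "c"),
        Metabolite("m_x", "orphan metabolite", "c"),
    ]
    rxns = [
        Reaction("r1", "r1", "Glycolysis", False, "", "m_pyr --> m_acc"),
        Reaction("r2", "r2", "Glycolysis", False, "", "m_pyr + m_atp -->"),
        Reaction("r3", "r3", "TCA cycle", False, "", "m_atp -->"),
        Reaction("r4", "r4", "TCA cycle", False, "", "m_acc -->"),
        Reaction("r5", "r5", "Extracellular transport", False, "", "m_x -->"),
    ]
    S = np.array([
        # r1   r2   r3   r4   r5
        [-1.0, -1.0, 0.0, 0.0, 0.0],   # pyruvate
        [0.0, -1.0, -1.0, 0.0, 0.0],   # ATP
        [1.0, 0.0, 0.0, -1.0, 0.0],    # acetyl-CoA (mito)
        [0.0, 1.0, 1.0, 0.0, 0.0],     # H2O
        [0.0, 0.0, 0.0, 0.0, -1.0],    # orphan
    ])
    return MetabolicModel("toy", mets, rxns, S, np.zeros(5), np.ones(5))


def module_of(ids, component=0, label="c1"):
    return Module(component, label, [(rid, 1.0) for rid in ids])


class TestReactionGraph:
    def test_shared_pyruvate_gives_labelled_edge(self, toy_model):
        g = build_reaction_graph([module_of(["r1", "r2"])], toy_model)
        assert g.has_edge("r1", "r2")
        assert g.edges["r1", "r2"]["shared_metabolites"] == "m_pyr"

    def test_ubiquitous_only_sharing_gives_no_edge(self, toy_model):
        # r2 and r3 share only ATP and H2O, both ubiquitous
        g = build_reaction_graph([module_of(["r2", "r3"])], toy_model)
        assert not g.has_edge("r2", "r3")
        assert g.number_of_edges() == 0

    def test_node_attributes_populated(self, toy_model):
        mods = [module_of(["r1", "r2"], 0), module_of(["r1"], 1)]
        g = build_reaction_graph(mods, toy_model, significant={"r2"})
        assert g.nodes["r1"]["module_count"] == 2
        assert g.nodes["r1"]["modules"] == "c1:1,c1:2"
        assert g.nodes["r1"]["subsystem"] == "Glycolysis"
        assert g.nodes["r1"]["equation"] == "m_pyr --> m_acc"
        assert g.nodes["r2"]["significant"] is True
        assert g.nodes["r1"]["significant"] is False

    def test_node_count_equals_module_union(self, toy_model):
        mods = [module_of(["r1", "r2"]), module_of(["r2", "r4"], 1)]
        g = build_reaction_graph(mods, toy_model)
        assert set(g.nodes) == {"r1", "r2", "r4"}

    def test_unknown_reaction_errors(self, toy_model):
        with pytest.raises(KeyError, match="ghost"):
            build_reaction_graph([module_of(["ghost"])], toy_model)

    def test_no_self_edges_single_edge_per_pair(self, toy_model):
        g = build_reaction_graph([module_of(["r1", "r2", "r4"])], toy_model)
        assert all(u != v for u, v in g.edges)
        assert isinstance(g, nx.Graph)  # simple graph: one edge per pair

    def test_no_edge_label_intersects_ubiquitous_list(self, toy_model):
        g = build_reaction_graph([module_of(["r1", "r2", "r3", "r4"])],
                                 toy_model)
        names = {m.id: m.name for m in toy_model.metabolites}
        for _, _, d in g.edges(data=True):
            shared = {names[mid] for mid in d["shared_metabolites"].split(",")}
            assert not shared & UBIQUITOUS_METABOLITES

    def test_hide_flag_for_transport(self, toy_model):
        g = build_reaction_graph([module_of(["r5"])], toy_model,
                                 hide_subsystems={"Extracellular transport"})
        assert g.nodes["r5"]["hidden"] is True


class TestFirstNeighbors:
    def test_outside_consumer_added_with_flag(self, toy_model):
        g = build_reaction_graph([module_of(["r1"])], toy_model)
        expanded = expand_first_neighbors(g, toy_model)
        # r2 shares pyruvate with r1, r4 shares acetyl-CoA
        assert set(expanded.nodes) == {"r1", "r2", "r4"}
        assert expanded.nodes["r2"]["first_neighbor"] is True
        assert expanded.nodes["r1"]["first_neighbor"] is False
        assert expanded.has_edge("r1", "r2")

    def test_closed_graph_unchanged(self, toy_model):
        g = build_reaction_graph([module_of(["r1", "r2", "r4"])], toy_model)
        expanded = expand_first_neighbors(g, toy_model)
        assert set(expanded.nodes) == set(g.nodes)
        assert set(expanded.edges) == set(g.edges)

    def test_neighbor_via_ubiquitous_not_added(self, toy_model):
        # r3 connects to r2 only through ATP/H2O
        g = build_reaction_graph([module_of(["r2"])], toy_model)
        expanded = expand_first_neighbors(g, toy_model)
        assert "r3" not in expanded.nodes


class TestMetabolicMap:
    def test_single_reaction_bipartite_shape(self, toy_model):
        g = build_reaction_graph([module_of(["r1"])], toy_model)
        bg = build_metabolic_map(g, ["Glycolysis"], toy_model)
        # r1: pyruvate -> acetyl-CoA, both non-ubiquitous: 3 nodes, 2 edges
        assert bg.number_of_nodes() == 3
        assert bg.number_of_edges() == 2
        assert bg.has_edge("m_pyr", "r1")   # substrate
        assert bg.has_edge("r1", "m_acc")   # product

    def test_compartment_attribute(self, toy_model):
        g = build_reaction_graph([module_of(["r1"])], toy_model)
        bg = build_metabolic_map(g, ["Glycolysis"], toy_model)
        assert bg.nodes["m_acc"]["compartment"] == "m"
        assert bg.nodes["m_acc"]["display_name"] == "acetyl-CoA [m]"

    def test_subsystem_filter(self, toy_model):
        mods = [module_of(["r1", "r2", "r4"])]
        g = build_reaction_graph(mods, toy_model)
        bg = build_metabolic_map(g, ["TCA cycle"], toy_model)
        rxn_nodes = [n for n, d in bg.nodes(data=True)
                     if d.get("kind") == "reaction"]
        assert rxn_nodes == ["r4"]

    def test_every_edge_joins_metabolite_and_reaction(self, toy_model):
        g = build_reaction_graph([module_of(["r1", "r2"])], toy_model)
        bg = build_metabolic_map(g, ["Glycolysis"], toy_model)
        for u, v in bg.edges:
            kinds = {bg.nodes[u]["kind"], bg.nodes[v]["kind"]}
            assert kinds == {"metabolite", "reaction"}

    def test_unknown_subsystem_errors(self, toy_model):
        g = build_reaction_graph([module_of(["r1"])], toy_model)
        with pytest.raises(KeyError, match="Nonsense"):
            build_metabolic_map(g, ["Nonsense"], toy_model)


class TestSingleModuleView:
    def test_induced_subgraph(self, toy_model):
        mods = [module_of(["r1", "r2"], 0), module_of(["r1", "r4"], 1)]
        g = build_reaction_graph(mods, toy_model)
        sub = single_module_view(g, "c1:2")
        assert set(sub.nodes) == {"r1", "r4"}
        assert set(sub.edges) <= set(g.edges)

    def test_single_reaction_module(self, toy_model):
        g = build_reaction_graph([module_of(["r5"])], toy_model)
        sub = single_module_view(g, "c1:1")
        assert list(sub.nodes) == ["r5"]
        assert sub.number_of_edges() == 0

    def test_unknown_module_errors(self, toy_model):
        g = build_reaction_graph([module_of(["r1"])], toy_model)
        with pytest.raises(KeyError):
            single_module_view(g, "c1:99")


class TestExportGraph:
    def test_tables_round_trip(self, toy_model, tmp_path):
        import pandas as pd

        mods = [module_of(["r1", "r2", "r4"])]
        g = build_reaction_graph(mods, toy_model, significant={"r1"})
        files = export_graph(g, tmp_path / "g", fmt="tables")
        nodes = pd.read_csv(files[0], sep=";")
        edges = pd.read_csv(files[1], sep=";")
        assert set(nodes["id"]) == set(g.nodes)
        assert {"module_count", "modules", "subsystem", "equation"} <= \
               set(nodes.columns)
        got = {tuple(sorted(e)) for e in zip(edges["source"], edges["target"])}
        assert got == {tuple(sorted(e)) for e in g.edges}

    def test_graphml_round_trip(self, toy_model, tmp_path):
        g = build_reaction_graph([module_of(["r1", "r2"])], toy_model)
        files = export_graph(g, tmp_path / "g", fmt="graphml")
        back = nx.read_graphml(files[0])
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        assert back.nodes["r1"]["subsystem"] == "Glycolysis"

    def test_exports_byte_stable(self, toy_model, tmp_path):
        mods = [module_of(["r1", "r2", "r4"])]
        g = build_reaction_graph(mods, toy_model)
        f1 = export_graph(g, tmp_path / "a", fmt="both")
        f2 = export_graph(g, tmp_path / "b", fmt="both")
        for a, b in zip(f1, f2):
            assert open(a, "rb").read() == open(b, "rb").read()

    def test_empty_graph_headers_only(self, tmp_path):
        g = nx.Graph()
        files = export_graph(g, tmp_path / "empty", fmt="tables")
        lines = open(files[0]).read().strip().splitlines()
        assert lines == ["id"]
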