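"""Reaction maps, metabolic maps and single-module views.

Modules become analysable networks in three forms:

* a reaction graph — reactions as nodes, an edge whenever two reactions
  share a reactant or product that is not a ubiquitous (currency)
  metabolite, with module/subsystem/equation attributes per node;
* a bipartite metabolite-reaction graph for subsystems of interest
  (the pathway-style metabolic map);
* induced single-module subgraphs.

Exports are semicolon-separated node/edge tables (Cytoscape-importable)
plus GraphML with identical content, deterministically ordered.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .decompose import Module
from .model_core import MetabolicModel

__all__ = [
    "UBIQUITOUS_METABOLITES",
    "build_reaction_graph",
    "expand_first_neighbors",
    "build_metabolic_map",
    "single_module_view",
    "export_graph",
]

#: Currency metabolites excluded from the connectivity calculation,
#: matched by base name irrespective of compartment.
UBIQUITOUS_METABOLITES = frozenset(
    {
        "CoA", "ubiquinol", "ubiquinone", "NH3", "O2", "H2O", "H+",
        "ATP", "ADP", "AMP", "dADP", "dATP", "Pi", "PPi",
        "CTP", "CDP", "CMP", "dCTP", "dCDP", "dCMP",
        "UTP", "UDP", "UMP", "dUTP", "dUDP", "dUMP",
        "GTP", "GDP", "GMP", "dGTP", "dGDP", "dGMP",
        "ITP", "IDP", "IMP", "dITP", "dIDP", "dIMP",
        "TTP", "TDP", "TMP", "dTTP", "dTDP", "dTMP",
        "NADH", "NADPH", "NAD+", "NADP+", "FADH2", "FAD",
        "CO2", "Na+", "HCO3-",
    }
)


def _is_ubiquitous(name: str, ubiquitous: frozenset[str] | set[str]) -> bool:
    return name in ubiquitous


def _shared_metabolites(
    model: MetabolicModel,
    ubiquitous: frozenset[str] | set[str],
) -> dict[str, set[str]]:
    """Map metabolite id -> reaction ids, dropping ubiquitous species."""
    by_met: dict[str, set[str]] = {}
    for mi, met in enumerate(model.metabolites):
        if _is_ubiquitous(met.name, ubiquitous):
            continue
        rxns = {model.reactions[j].id for j in range(model.n_reactions)
                if model.S[mi, j] != 0}
        if rxns:
            by_met[met.id] = rxns
    return by_met


def build_reaction_graph(
    modules: list[Module],
    model: MetabolicModel,
    ubiquitous: frozenset[str] | set[str] = UBIQUITOUS_METABOLITES,
    significant: set[str] | None = None,
    hide_subsystems: set[str] | None = None,
) -> nx.Graph:
    """Reaction-reaction graph over the union of module reactions.

    Two reactions are connected iff they share at least one non-ubiquitous
    metabolite; the edge is labelled with every shared metabolite id. Node
    attributes: module count, module list, subsystem, chemical equation,
    condition tag, significance flag, first-neighbour flag and an optional
    hide flag (extracellular-transport nodes are flagged, not removed).
    """
    membership: dict[str, list[str]] = {}
    conditions: dict[str, set[str]] = {}
    for mod in modules:
        tag = f"{mod.condition_label}:{mod.component + 1}"
        for rid in mod.reaction_ids:
            model.reaction_index(rid)  # KeyError on unknown id
            membership.setdefault(rid, []).append(tag)
            conditions.setdefault(rid, set()).add(mod.condition_label)

    g = nx.Graph()
    significant = significant or set()
    hide_subsystems = hide_subsystems or set()
    rxn_by_id = {r.id: r for r in model.reactions}
    for rid, tags in membership.items():
        r = rxn_by_id[rid]
        g.add_node(
            rid,
            module_count=len(tags),
            modules=",".join(sorted(tags)),
            subsystem=r.subsystem,
            equation=r.equation,
            condition=",".join(sorted(conditions[rid])),
            significant=rid in significant,
            first_neighbor=False,
            hidden=r.subsystem in hide_subsystems,
        )
    _add_shared_metabolite_edges(g, model, ubiquitous)
    return g


def _add_shared_metabolite_edges(g, model, ubiquitous) -> None:
    nodes = set(g.nodes)
    for met_id, rxns in _shared_metabolites(model, ubiquitous).items():
        present = sorted(rxns & nodes)
        for i, ra in enumerate(present):
            for rb in present[i + 1:]:
                if g.has_edge(ra, rb):
                    shared = set(g.edges[ra, rb]["shared_metabolites"].split(","))
                    shared.add(met_id)
                    g.edges[ra, rb]["shared_metabolites"] = ",".join(sorted(shared))
                else:
                    g.add_edge(ra, rb, shared_metabolites=met_id)


def expand_first_neighbors(
    g: nx.Graph,
    model: MetabolicModel,
    ubiquitous: frozenset[str] | set[str] = UBIQUITOUS_METABOLITES,
) -> nx.Graph:
    """Add model reactions sharing a non-ubiquitous metabolite with the graph.

    Added nodes are flagged ``first_neighbor``; edges are recomputed over
    the enlarged node set. A graph already closed under the neighbourhood
    relation is returned unchanged (as a copy).
    """
    g = g.copy()
    current = set(g.nodes)
    by_met = _shared_metabolites(model, ubiquitous)
    neighbours: set[str] = set()
    for rxns in by_met.values():
        if rxns & current:
            neighbours |= rxns - current
    rxn_by_id = {r.id: r for r in model.reactions}
    for rid in sorted(neighbours):
        r = rxn_by_id[rid]
        g.add_node(
            rid,
            module_count=0,
            modules="",
            subsystem=r.subsystem,
            equation=r.equation,
            condition="",
            significant=False,
            first_neighbor=True,
            hidden=False,
        )
    # recompute edges over the expanded node set
    g.remove_edges_from(list(g.edges))
    _add_shared_metabolite_edges(g, model, ubiquitous)
    return g


def build_metabolic_map(
    g: nx.Graph,
    subsystems: list[str],
    model: MetabolicModel,
    ubiquitous: frozenset[str] | set[str] = UBIQUITOUS_METABOLITES,
    show_ubiquitous: bool = False,
) -> nx.DiGraph:
    """Bipartite metabolite-reaction map of selected subsystems.

    Reactions of the graph annotated to ``subsystems`` are extracted with
    their metabolites (ubiquitous ones excluded from display by default);
    substrate edges run metabolite -> reaction and product edges
    reaction -> metabolite, with compartment attributes on metabolites.
    """
    known = {r.subsystem for r in model.reactions}
    missing = [s for s in subsystems if s not in known]
    if missing:
        raise KeyError(f"unknown subsystems: {missing}")
    wanted = set(subsystems)
    selected = [rid for rid, data in g.nodes(data=True)
                if data.get("subsystem") in wanted]
    if not selected:
        raise ValueError("no reactions in the selected subsystems")

    bg = nx.DiGraph()
    for rid in sorted(selected):
        j = model.reaction_index(rid)
        r = model.reactions[j]
        bg.add_node(rid, kind="reaction", subsystem=r.subsystem,
                    equation=r.equation)
        for mi in range(model.n_metabolites):
            coef = model.S[mi, j]
            if coef == 0:
                continue
            met = model.metabolites[mi]
            if not show_ubiquitous and _is_ubiquitous(met.name, ubiquitous):
                continue
            if met.id not in bg:
                bg.add_node(met.id, kind="metabolite", name=met.name,
                            compartment=met.compartment,
                            display_name=met.display_name)
            if coef < 0:
                bg.add_edge(met.id, rid, role="substrate", coefficient=-coef)
            else:
                bg.add_edge(rid, met.id, role="product", coefficient=coef)
    return bg


def single_module_view(g: nx.Graph, module_id: str) -> nx.Graph:
    """Induced subgraph on the reactions of one module (tag ``cond:index``)."""
    members = [rid for rid, data in g.nodes(data=True)
               if module_id in (data.get("modules") or "").split(",")]
    if not members:
        raise KeyError(f"module {module_id!r} not present in the graph")
    return g.subgraph(members).copy()


def export_graph(g: nx.Graph | nx.DiGraph, basepath, fmt: str = "both") -> list[str]:
    """Write semicolon-separated node/edge tables and/or GraphML.

    ``basepath`` is extended with ``_nodes.csv`` / ``_edges.csv`` /
    ``.graphml``. Rows are sorted lexicographically so exports are
    byte-stable. Returns the list of files written.
    """
    basepath = str(basepath)
    written = []
    if fmt not in {"tables", "graphml", "both", "sif"}:
        raise ValueError(f"unknown export format {fmt!r}")

    node_attrs = sorted({k for _, d in g.nodes(data=True) for k in d})
    node_rows = []
    for node in sorted(g.nodes):
        row = {"id": node}
        row.update({k: g.nodes[node].get(k, "") for k in node_attrs})
        node_rows.append(row)
    edge_attrs = sorted({k for *_, d in g.edges(data=True) for k in d})
    edge_rows = []
    for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1])):
        a, b = (u, v) if g.is_directed() else tuple(sorted((u, v)))
        row = {"source": a, "target": b}
        row.update({k: d.get(k, "") for k in edge_attrs})
        edge_rows.append(row)

    if fmt in {"tables", "both"}:
        npath, epath = basepath + "_nodes.csv", basepath + "_edges.csv"
        pd.DataFrame(node_rows, columns=["id"] + node_attrs).to_csv(
            npath, sep=";", index=False)
        pd.DataFrame(edge_rows, columns=["source", "target"] + edge_attrs).to_csv(
            epath, sep=";", index=False)
        written += [npath, epath]
    if fmt in {"graphml", "both"}:
        gpath = basepath + ".graphml"
        # GraphML needs scalar attribute values; booleans are supported
        ordered = nx.DiGraph() if g.is_directed() else nx.Graph()
        for row in node_rows:
            ordered.add_node(row["id"], **{k: row[k] for k in node_attrs})
        for row in edge_rows:
            ordered.add_edge(row["source"], row["target"],
                             **{k: row[k] for k in edge_attrs})
        nx.write_graphml(ordered, gpath)
        written.append(gpath)
    if fmt == "sif":
        spath = basepath + ".sif"
        with open(spath, "w") as fh:
            linked = set()
            for row in edge_rows:
                fh.write(f"{row['source']}\tshares\t{row['target']}\n")
                linked |= {row["source"], row["target"]}
            for row in node_rows:
                if row["id"] not in linked:
                    fh.write(f"{row['id']}\n")
        written.append(spath)
    return written
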