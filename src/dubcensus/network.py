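"""Merging interaction calls with a curated physical-interaction edge list.

The merged object is a multigraph: AP-MS edges (bait to prey, weighted by
mean TSC) and curated edges (from a literature database such as BioGRID)
coexist as parallel edges with distinct provenance, mirroring the dual
edge-color convention of the published network diagrams. Curated edges are
restricted to the induced subgraph of called proteins — they never introduce
new nodes. AP-MS edge display widths grow monotonically with TSC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

ROLES = ("bait_dub", "validated_partner", "other")


@dataclass(frozen=True)
class CuratedEdge:
    """One undirected curated physical interaction."""

    protein_a: str
    protein_b: str
    source: str = "curated"
    interaction_type: str = "physical"

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise ValueError("self-loops are not retained")


def curated_edges_from_table(df: pd.DataFrame) -> list[CuratedEdge]:
    edges = []
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            continue
        source = str(row[2]) if len(row) > 2 else "curated"
        edges.append(CuratedEdge(a, b, source))
    return edges


def merge_networks(
    calls: pd.DataFrame,
    curated: Iterable[CuratedEdge] = (),
    validated: pd.DataFrame | None = None,
) -> nx.MultiGraph:
    """Build the role-annotated multigraph from calls plus curated edges.

    ``calls`` needs columns bait, prey, mean_tsc (the shaded table, usually
    restricted to non-gray rows upstream). Curated edges are added only
    between proteins already present as nodes.
    """
    g = nx.MultiGraph()
    validated_pairs = set()
    if validated is not None and len(validated):
        validated_pairs = set(zip(validated["bait"], validated["prey"]))

    for row in calls.itertuples(index=False):
        g.add_node(row.bait, role="bait_dub")
    for row in calls.itertuples(index=False):
        if row.prey not in g:
            g.add_node(row.prey, role="other")
        # roles are ordered bait_dub > validated_partner > other; never downgrade
        if (
            g.nodes[row.prey]["role"] == "other"
            and (row.bait, row.prey) in validated_pairs
        ):
            g.nodes[row.prey]["role"] = "validated_partner"
        g.add_edge(row.bait, row.prey, provenance="apms", weight=float(row.mean_tsc))

    for edge in curated:
        if edge.protein_a in g and edge.protein_b in g:
            g.add_edge(
                edge.protein_a,
                edge.protein_b,
                provenance="curated",
                source=edge.source,
            )
    return g


def weight_edges(graph: nx.MultiGraph) -> nx.MultiGraph:
    """Assign display widths: log-scaled in TSC for AP-MS edges, unit width
    for curated edges. Monotone nondecreasing in TSC."""
    for _u, _v, data in graph.edges(data=True):
        if data.get("provenance") == "apms":
            tsc = data.get("weight", 0.0)
            if tsc <= 0:
                raise ValueError("AP-MS edge with nonpositive TSC")
            data["width"] = 1.0 + math.log1p(tsc)
        else:
            data["width"] = 1.0
    return graph


def export_graph(graph: nx.MultiGraph, path, fmt: str = "graphml") -> None:
    """Write the graph as GraphML (lossless), SIF (topology + provenance),
    or an edge-attribute TSV."""
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in graph.edges(data=True):
                fh.write(f"{u}\t{data.get('provenance', 'edge')}\t{v}\n")
    elif fmt == "edge_tsv":
        rows = [
            {
                "protein_a": u,
                "protein_b": v,
                "provenance": data.get("provenance", ""),
                "weight": data.get("weight", ""),
                "width": data.get("width", ""),
            }
            for u, v, data in graph.edges(data=True)
        ]
        pd.DataFrame(
            rows, columns=["protein_a", "protein_b", "provenance", "weight", "width"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def import_graphml(path) -> nx.MultiGraph:
    g = nx.read_graphml(path, force_multigraph=True)
    return nx.MultiGraph(g)
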