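"""Confidence-thresholded association networks and their exports.

Aggregated associations become typed graphs: nodes are normalized entities
(or surface-keyed nodes when normalization failed), edges carry the
semantic group, relation type, polarity and confidence score. Edge weight
equals Sconf so renderers can map thickness to confidence; polarity is an
edge attribute so negated evidence stays visually distinct. Thresholding is
inclusive (Sconf >= tau).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .aggregation import AggregatedAssociation
from .patterns import SemanticGroup

__all__ = [
    "threshold_filter",
    "retention_table",
    "build_graph",
    "export_graph",
    "import_graph",
    "NODE_CLASSES",
]

NODE_CLASSES = ("ACE_INHIBITOR", "OTHER_CHEMICAL", "GENE_PROTEIN", "DISEASE")


def threshold_filter(
    aggregated: Sequence[AggregatedAssociation], tau: float
) -> list[AggregatedAssociation]:
    """Associations with Sconf >= tau, original order preserved."""
    if tau < 0:
        raise ValueError("threshold must be non-negative")
    return [a for a in aggregated if a.s_conf >= tau]


def retention_table(
    aggregated: Sequence[AggregatedAssociation], taus: Sequence[float]
) -> pd.DataFrame:
    """Retained-association counts per semantic group at each threshold.

    Rows follow the given ascending threshold grid; every group column is
    non-increasing down the rows.
    """
    if list(taus) != sorted(taus):
        raise ValueError("thresholds must be ascending")
    rows = []
    for tau in taus:
        kept = threshold_filter(aggregated, tau)
        row = {"threshold": tau}
        for group in SemanticGroup:
            row[group.value] = sum(1 for a in kept if a.group is group)
        rows.append(row)
    return pd.DataFrame(rows)


def _node_attrs(
    identifier: str, node_class: str, normalized: bool, label: str
) -> dict:
    return {
        "label": label,
        "node_class": node_class,
        "normalized": normalized,
    }


def build_graph(
    aggregated: Sequence[AggregatedAssociation],
    node_classes: Mapping[str, str] | None = None,
    labels: Mapping[str, str] | None = None,
) -> nx.MultiDiGraph:
    """Build the association graph.

    Nodes are keyed by identifier (normalized entities) or case-folded
    surface (unnormalized ones, carried through with ``normalized=False``).
    ``node_classes`` maps node keys to one of ``NODE_CLASSES`` (defaults to
    OTHER_CHEMICAL-style inference by namespace prefix is not attempted;
    unknown keys get "OTHER_CHEMICAL" for chemical-pair groups and the
    group-implied class otherwise). Edge attributes: group, relation_type,
    polarity, s_conf and width_weight (= s_conf). Self-loops never occur
    because co-administration requires two distinct chemicals.
    """
    node_classes = dict(node_classes or {})
    labels = dict(labels or {})
    g = nx.MultiDiGraph()
    for a in aggregated:
        implied_b = {
            SemanticGroup.MECHANISMS: "GENE_PROTEIN",
            SemanticGroup.EFFECTS: "DISEASE",
            SemanticGroup.COADMINISTRATION: "OTHER_CHEMICAL",
        }[a.group]
        for ident, default_class in (
            (a.identifier_a, "OTHER_CHEMICAL"),
            (a.identifier_b, implied_b),
        ):
            if ident not in g:
                g.add_node(
                    ident,
                    **_node_attrs(
                        ident,
                        node_classes.get(ident, default_class),
                        not ident.startswith("surface:"),
                        labels.get(ident, ident),
                    ),
                )
        if a.identifier_a == a.identifier_b:
            continue  # defensive: no self-loops
        g.add_edge(
            a.identifier_a,
            a.identifier_b,
            group=a.group.value,
            relation_type=a.relation_type,
            polarity=a.polarity.value,
            s_conf=float(a.s_conf),
            width_weight=float(a.s_conf),
        )
    return g


def export_graph(graph: nx.MultiDiGraph, path: str, fmt: str = "graphml") -> None:
    """Write the graph as GraphML or a flat edge-list TSV."""
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "edgelist":
        rows = []
        for u, v, data in graph.edges(data=True):
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "group": data["group"],
                    "relation_type": data["relation_type"],
                    "polarity": data["polarity"],
                    "s_conf": repr(data["s_conf"]),
                    "source_class": graph.nodes[u]["node_class"],
                    "target_class": graph.nodes[v]["node_class"],
                    "source_normalized": int(graph.nodes[u]["normalized"]),
                    "target_normalized": int(graph.nodes[v]["normalized"]),
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "source", "target", "group", "relation_type", "polarity",
                "s_conf", "source_class", "target_class",
                "source_normalized", "target_normalized",
            ],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_graph(path: str, fmt: str = "graphml") -> nx.MultiDiGraph:
    """Re-load an exported graph with all attributes."""
    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        return nx.MultiDiGraph(g)
    if fmt == "edgelist":
        df = pd.read_csv(path, sep="\t")
        g = nx.MultiDiGraph()
        for _, row in df.iterrows():
            for node, cls_col, norm_col in (
                (row["source"], "source_class", "source_normalized"),
                (row["target"], "target_class", "target_normalized"),
            ):
                if node not in g:
                    g.add_node(
                        node, label=node, node_class=row[cls_col],
                        normalized=bool(row[norm_col]),
                    )
            g.add_edge(
                row["source"], row["target"], group=row["group"],
                relation_type=row["relation_type"], polarity=row["polarity"],
                s_conf=float(row["s_conf"]), width_weight=float(row["s_conf"]),
            )
        return g
    raise ValueError(f"unknown import format {fmt!r}")
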