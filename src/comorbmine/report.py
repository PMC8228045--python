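"""Bipartite item/rule network export of a ranked rule table.

Each mined rule becomes its own vertex (carrying support and lift for
downstream sizing/coloring), with edges antecedent-item → rule → consequent-
item. This arulesViz-style representation renders multi-antecedent rules
faithfully, which plain item-to-item edges cannot.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Sequence, Union

import networkx as nx

from .mining import AssociationRule, RuleMetrics

__all__ = ["build_rule_graph", "export_graph"]


def build_rule_graph(
    ranked: Sequence[tuple[AssociationRule, RuleMetrics]],
    labels: dict[str, str] | None = None,
) -> nx.DiGraph:
    """Directed bipartite graph over a ranked rule list.

    Item vertices are block identifiers (alphabetical insertion order); rule
    vertices are ``r1, r2, ...`` in rank order with ``support`` and ``lift``
    as numeric attributes. Every rule vertex has in-degree = antecedent size
    and out-degree 1.
    """
    if not ranked:
        raise ValueError("cannot build a graph from an empty rule list")
    labels = labels or {}
    g = nx.DiGraph()
    items = sorted(
        {i for rule, _ in ranked for i in rule.antecedent} | {rule.consequent for rule, _ in ranked}
    )
    for item in items:
        g.add_node(item, kind="item", label=labels.get(item, item))
    for rank, (rule, metrics) in enumerate(ranked, start=1):
        rid = f"r{rank}"
        g.add_node(
            rid,
            kind="rule",
            label=rule.label,
            support=float(metrics.support),
            lift=float(metrics.lift),
        )
        for item in sorted(rule.antecedent):
            g.add_edge(item, rid)
        g.add_edge(rid, rule.consequent)
    return g


def export_graph(graph: nx.DiGraph, path: Union[str, Path]) -> None:
    """Write the rule graph as GraphML, atomically and deterministically.

    Vertex order is insertion order (items alphabetical, rules by rank), so
    two runs on the same input produce byte-identical files. Rule vertices
    missing ``support`` or ``lift`` are rejected before anything is written.
    """
    for node, data in graph.nodes(data=True):
        kind = data.get("kind")
        if kind not in ("item", "rule"):
            raise ValueError(f"vertex {node!r} lacks a valid 'kind' attribute")
        if not data.get("label"):
            raise ValueError(f"vertex {node!r} lacks a label")
        if kind == "rule" and ("support" not in data or "lift" not in data):
            raise ValueError(f"rule vertex {node!r} lacks support/lift attributes")
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".graphml.tmp")
    try:
        os.close(fd)
        nx.write_graphml(graph, tmp, named_key_ids=True)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
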