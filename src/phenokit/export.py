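"""Human-readable exports: DNF decision trees, GraphML, tabular reports.

A combined phenotype class with several restricted subclasses (e.g., the five
T2DM case classes) can be drawn as a decision tree: each subclass's Boolean
expression is converted to disjunctive normal form, each conjunction becomes
one root-to-leaf path (internal nodes ask about one restricted class, edges
are labelled ``yes``/``no``), and paths sharing a literal prefix share nodes.
Only topology and labels are emitted — layout is left to downstream viewers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import networkx as nx

from .errors import ModelError
from .expressions import Conjunction, to_dnf
from .model import (
    CombinedPhenotypeClass,
    PhenotypeModel,
    RestrictedCombinedClass,
)
from .reasoner import REPORT_HEADER

__all__ = [
    "DecisionTree",
    "build_decision_tree",
    "write_graphml",
    "read_graphml",
    "write_report",
    "read_report_csv",
]


@dataclass(frozen=True)
class DecisionTree:
    """A decision tree over restricted-class literals.

    ``nodes`` maps node id to (label, kind) with kind ``root``/``decision``/
    ``leaf``; ``edges`` are (parent, child, branch label) triples where the
    branch label is ``yes``/``no`` for the literal polarity of the parent
    decision node (or empty below the root). ``leaves`` maps leaf node ids to
    the restricted combined class they classify into.
    """

    root: str
    nodes: Dict[str, Tuple[str, str]]
    edges: Tuple[Tuple[str, str, str], ...]
    leaves: Dict[str, str]

    def leaf_paths(self) -> List[Tuple[str, Conjunction]]:
        """(class name, conjunction) per root-to-leaf path, canonically sorted."""
        children: Dict[str, List[Tuple[str, str]]] = {}
        for parent, child, label in self.edges:
            children.setdefault(parent, []).append((child, label))
        out: List[Tuple[str, Conjunction]] = []

        def walk(node: str, literals: Tuple[Tuple[str, bool], ...]):
            if node in self.leaves:
                out.append((self.leaves[node], tuple(sorted(literals))))
                return
            label, _ = self.nodes[node]
            for child, branch in children.get(node, []):
                extra = () if node == self.root else ((label, branch == "no"),)
                walk(child, literals + extra)

        walk(self.root, ())
        return sorted(out)


def build_decision_tree(model: PhenotypeModel, ncop_name: str) -> DecisionTree:
    """Build the decision tree of one combined phenotype class.

    Deterministic: literals within each conjunction are ordered by first
    appearance of their atom across the subclasses' DNFs (scanning subclasses
    in registry order), so paths that share leading decisions share nodes.
    """
    ncop = model[ncop_name]
    if not isinstance(ncop, CombinedPhenotypeClass):
        raise ModelError(f"{ncop_name!r} is not a combined phenotype class")
    subclasses = [
        c for c in model.subclasses_of(ncop_name) if isinstance(c, RestrictedCombinedClass)
    ]
    if not subclasses:
        raise ModelError(f"{ncop_name!r} has no restricted subclasses")

    dnfs = [(sub, to_dnf(sub.expression)) for sub in subclasses]
    atom_order: Dict[str, int] = {}
    for _, conjs in dnfs:
        for conj in conjs:
            for atom, _neg in conj:
                atom_order.setdefault(atom, len(atom_order))

    nodes: Dict[str, Tuple[str, str]] = {}
    edges: List[Tuple[str, str, str]] = []
    leaves: Dict[str, str] = {}
    node_ids: Dict[object, str] = {}

    def node_for(key, label, kind) -> str:
        if key not in node_ids:
            nid = f"n{len(node_ids)}"
            node_ids[key] = nid
            nodes[nid] = (label, kind)
        return node_ids[key]

    root = node_for(("root",), ncop_name, "root")
    for sub, conjs in dnfs:
        for conj in conjs:
            ordered = sorted(conj, key=lambda lit: atom_order[lit[0]])
            prev, branch = root, ""
            prefix: Tuple = ()
            for atom, negated in ordered:
                node = node_for(("decision", prefix, atom), atom, "decision")
                edge = (prev, node, branch)
                if edge not in edges:
                    edges.append(edge)
                prev = node
                branch = "no" if negated else "yes"
                prefix = prefix + ((atom, negated),)
            leaf = node_for(("leaf", prefix, sub.name), sub.name, "leaf")
            edge = (prev, leaf, branch)
            if edge not in edges:
                edges.append(edge)
            leaves[leaf] = sub.name
    return DecisionTree(root=root, nodes=nodes, edges=tuple(edges), leaves=leaves)


def _to_nx(tree: DecisionTree) -> "nx.DiGraph":
    g = nx.DiGraph()
    for nid, (label, kind) in tree.nodes.items():
        g.add_node(nid, label=label, kind=kind)
    for parent, child, label in tree.edges:
        g.add_edge(parent, child, label=label)
    return g


def write_graphml(tree: DecisionTree, path: Union[str, Path]) -> None:
    """Write the tree as GraphML (topology + labels, no coordinates)."""
    if not tree.leaves:
        raise ModelError("refusing to write a decision tree without leaves")
    nx.write_graphml(_to_nx(tree), str(path))


def read_graphml(path: Union[str, Path]) -> DecisionTree:
    """Read a GraphML decision tree back (round-trips :func:`write_graphml`)."""
    g = nx.read_graphml(str(path))
    nodes = {nid: (data["label"], data["kind"]) for nid, data in g.nodes(data=True)}
    roots = [nid for nid, (_, kind) in nodes.items() if kind == "root"]
    if len(roots) != 1:
        raise ModelError("GraphML document is not a phenotype decision tree")
    edges = tuple(
        (parent, child, data.get("label", "")) for parent, child, data in g.edges(data=True)
    )
    leaves = {nid: label for nid, (label, kind) in nodes.items() if kind == "leaf"}
    return DecisionTree(root=roots[0], nodes=nodes, edges=edges, leaves=leaves)


# ---------------------------------------------------------------------------
# Tabular reasoner reports
# ---------------------------------------------------------------------------


def write_report(
    rows: Sequence[Tuple[str, str, Tuple[str, ...]]],
    path: Union[str, Path],
    format: str = "csv",
) -> None:
    """Write reasoner report rows as CSV (canonical) or XLSX.

    Three columns: Type, Non-restricted, Restricted; inferred restricted
    class names are joined with "; " in the third column.
    """
    path = Path(path)
    flat = [(t, nr, "; ".join(r)) for t, nr, r in rows]
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(REPORT_HEADER)
            writer.writerows(flat)
    elif format == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "Reasoner report"
        ws.append(list(REPORT_HEADER))
        for row in flat:
            ws.append(list(row))
        wb.save(str(path))
    else:
        raise ModelError(f"unknown report format {format!r}")


def read_report_csv(path: Union[str, Path]) -> List[Tuple[str, str, Tuple[str, ...]]]:
    """Read back a CSV report (round-trips :func:`write_report`)."""
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != REPORT_HEADER:
            raise ModelError(f"unexpected report header {header!r}")
        return [
            (t, nr, tuple(x for x in r.split("; ") if x))
            for t, nr, r in reader
        ]
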