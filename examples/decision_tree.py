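"""Export the T2DM case classes as a DNF decision tree in GraphML.

Each case class's Boolean expression is converted to disjunctive normal form;
every conjunction becomes one root-to-leaf path, and paths sharing leading
literals share nodes. The GraphML file contains topology and labels only —
open it in a graph editor with automatic layout to see the flowchart.
"""

from pathlib import Path

from phenokit import build_decision_tree, build_t2dm_fixture, write_graphml

model = build_t2dm_fixture()
tree = build_decision_tree(model, "T2DM_Case")

print(f"decision nodes + leaves + root: {len(tree.nodes)}")
print(f"leaves (one per case class): {sorted(set(tree.leaves.values()))}")
print("root-to-leaf paths (leaf class: literals):")
for leaf_cls, conj in tree.leaf_paths():
    literals = " AND ".join(("NOT " if neg else "") + atom for atom, neg in conj)
    print(f"  {leaf_cls}: {literals}")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = out / "t2dm_case_tree.graphml"
write_graphml(tree, path)
print(f"\nwrote {path}")
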