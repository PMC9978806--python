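"""Thin helpers over dendropy for rooted, dated species trees.

Branch lengths are in million years. Internal nodes without labels get
deterministic labels N1, N2, ... in postorder so that edges and ancestral
tables can be keyed by name.
"""

from __future__ import annotations

from pathlib import Path

import dendropy


def load_dated_tree(source: "str | Path | dendropy.Tree") -> dendropy.Tree:
    """Load (or adopt) a rooted dated tree and validate/label it."""
    if isinstance(source, dendropy.Tree):
        tree = source
    else:
        text = str(source)
        if "(" in text and ";" in text:
            tree = dendropy.Tree.get(data=text, schema="newick")
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick")
    tree.is_rooted = True
    counter = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label.replace(" ", "_") if node.taxon else node.label
        elif not node.label:
            counter += 1
            node.label = f"N{counter}"
        if node.parent_node is not None:
            if node.edge.length is None or node.edge.length <= 0:
                raise ValueError(
                    f"non-positive branch length on edge to {node.label!r}"
                )
    labels = [n.label for n in tree.postorder_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate node labels in tree")
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [n.label for n in tree.leaf_node_iter()]


def edges(tree: dendropy.Tree) -> list[tuple[str, str, float]]:
    """(parent_label, child_label, length_my) for every non-root edge."""
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            out.append((node.parent_node.label, node.label, float(node.edge.length)))
    return out


def node_by_label(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if node.label == label:
            return node
    raise KeyError(label)
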