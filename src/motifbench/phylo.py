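"""Phylogenies with proximity-parameterized branches.

Each branch carries a proximity q in (0, 1]: the probability that a
base is copied unchanged from parent to child over that branch (the
complement is redrawn from the equilibrium distribution; see
:mod:`motifbench.evolve`).  Proximities compose multiplicatively along
root-to-leaf paths.  Trees can equivalently be read from Newick files
annotated with expected substitutions per site, converted through the
F81 relation q = exp(-beta t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class TreeNode:
    label: str | None = None
    proximity: float | None = None  # None only at the root
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree whose non-root nodes carry an incoming-edge proximity."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        if self.root.proximity is not None:
            raise ValueError("root must not carry an edge proximity")
        labels = []
        for node in self.preorder():
            if node is not self.root:
                q = node.proximity
                if q is None or not (0.0 < q <= 1.0):
                    raise ValueError(f"edge proximity {q!r} outside (0, 1]")
            if node.is_leaf:
                if not node.label:
                    raise ValueError("every leaf must be labelled")
                labels.append(node.label)
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def path_proximity(self, leaf: str) -> float:
        """Product of edge proximities on the root-to-leaf path."""

        def search(node: TreeNode, acc: float) -> float | None:
            q = acc if node.proximity is None else acc * node.proximity
            if node.is_leaf and node.label == leaf:
                return q
            for child in node.children:
                found = search(child, q)
                if found is not None:
                    return found
            return None

        q = search(self.root, 1.0)
        if q is None:
            raise KeyError(f"unknown leaf {leaf!r}")
        return q

    def __len__(self) -> int:
        return len(self.leaves())


def branch_length_to_proximity(t: float, equilibrium: np.ndarray | None = None) -> float:
    """Convert an F81 branch length (expected substitutions per site) to
    a proximity: q = exp(-beta t) with beta = 1 / (1 - sum pi_b^2).
    Uniform equilibrium gives beta = 4/3 (Jukes-Cantor)."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    beta = _f81_beta(equilibrium)
    return float(np.exp(-beta * t))


def proximity_to_branch_length(q: float, equilibrium: np.ndarray | None = None) -> float:
    """Inverse of :func:`branch_length_to_proximity`."""
    if not 0.0 < q <= 1.0:
        raise ValueError("proximity must lie in (0, 1]")
    beta = _f81_beta(equilibrium)
    return float(-np.log(q) / beta)


def _f81_beta(equilibrium: np.ndarray | None) -> float:
    if equilibrium is None:
        return 4.0 / 3.0
    pi = np.asarray(equilibrium, dtype=float)
    return 1.0 / (1.0 - float((pi**2).sum()))


def parse_newick(
    text: str,
    branch_mode: str = "proximity",
    equilibrium: np.ndarray | None = None,
) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    ``branch_mode="proximity"`` reads branch values directly as
    proximities in (0, 1]; ``"distance"`` reads them as expected
    substitutions per site and converts via
    :func:`branch_length_to_proximity`.
    """
    if branch_mode not in ("proximity", "distance"):
        raise ValueError(f"unknown branch_mode {branch_mode!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode, is_root: bool) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        if is_root:
            q = None
        else:
            length = dnode.edge.length
            if length is None:
                raise ValueError(f"missing branch value on edge above {label or 'internal node'}")
            if branch_mode == "proximity":
                if not 0.0 < length <= 1.0:
                    raise ValueError(f"proximity {length} outside (0, 1]")
                q = float(length)
            else:
                q = branch_length_to_proximity(float(length), equilibrium)
        node = TreeNode(label=label, proximity=q)
        node.children = [convert(c, False) for c in dnode.child_nodes()]
        return node

    return PhyloTree(convert(dtree.seed_node, True))


def write_newick(
    tree: PhyloTree,
    branch_mode: str = "proximity",
    equilibrium: np.ndarray | None = None,
) -> str:
    """Serialise a tree to Newick with branch values as proximities or
    as F81 substitution distances."""
    if branch_mode not in ("proximity", "distance"):
        raise ValueError(f"unknown branch_mode {branch_mode!r}")

    def fmt(node: TreeNode) -> str:
        label = node.label or ""
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            body = f"({inner}){label}"
        else:
            body = label
        if node.proximity is None:
            return body
        value = (
            node.proximity
            if branch_mode == "proximity"
            else proximity_to_branch_length(node.proximity, equilibrium)
        )
        return f"{body}:{value:.12g}"

    return fmt(tree.root) + ";"


def star_tree(proximities, labels=None) -> PhyloTree:
    """Star phylogeny: every leaf hangs directly off the root.

    With ``labels=None`` the first leaf is named ``REF`` (the reference
    ortholog) and the rest ``S1``, ``S2``, ...
    """
    proximities = list(proximities)
    if labels is None:
        labels = ["REF"] + [f"S{i}" for i in range(1, len(proximities))]
    labels = list(labels)
    if len(labels) != len(proximities):
        raise ValueError("proximities and labels must have equal length")
    root = TreeNode(label="root")
    root.children = [TreeNode(label=l, proximity=q) for l, q in zip(labels, proximities)]
    return PhyloTree(root)
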