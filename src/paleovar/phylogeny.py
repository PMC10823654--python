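"""Species-tree utilities.

The cross-species arm of the pipeline interprets allele sharing against a
fixed, rooted species tree (the kind of tree that ships with a multiple
whole-genome alignment, with branch lengths in substitutions per site).
This module parses that tree, computes patristic distances between leaves,
and produces the deterministic display order used for per-species tables
("heatmap order": the reference-containing clade first, then progressively
more distant clades, preserving the child order written in the newick).

Trees are consumed as written: no re-rooting and no ladderization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = ["PhyloTree", "parse_newick", "patristic_distance", "heatmap_order"]


@dataclass
class PhyloTree:
    """A rooted species tree with a designated reference ("human-analog") leaf.

    Wraps a :class:`dendropy.Tree`; leaf names must be unique and branch
    lengths non-negative.
    """

    tree: dendropy.Tree
    reference: str | None = None
    _pdm: object = field(default=None, repr=False, compare=False)

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def __post_init__(self) -> None:
        names = self.leaf_names
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf names in tree: {sorted(dupes)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length in tree")
        if self.reference is not None and self.reference not in names:
            raise ValueError(f"reference leaf {self.reference!r} not in tree")

    def distance(self, a: str, b: str) -> float:
        return patristic_distance(self, a, b)

    def distance_table(self) -> pd.DataFrame:
        """All-pairs patristic distance matrix as a DataFrame."""
        names = self.leaf_names
        return pd.DataFrame(
            [[patristic_distance(self, a, b) for b in names] for a in names],
            index=names,
            columns=names,
        )

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_newick(text: str, reference: str | None = None) -> PhyloTree:
    """Parse a newick string (or open handle) into a :class:`PhyloTree`.

    Unlabeled internal nodes are allowed.  Malformed input raises
    ``ValueError`` carrying dendropy's character-position diagnostics.
    """
    if hasattr(text, "read"):
        text = text.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"newick parse error: {exc}") from exc
    return PhyloTree(tree=tree, reference=reference)


def _leaf(ptree: PhyloTree, name: str) -> dendropy.Node:
    for lf in ptree.tree.leaf_node_iter():
        if lf.taxon.label == name:
            return lf
    raise KeyError(f"leaf {name!r} not in tree")


def patristic_distance(ptree: PhyloTree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves.

    Symmetric; zero iff ``leaf_a == leaf_b``.  Unknown leaves raise KeyError.
    """
    a, b = _leaf(ptree, leaf_a), _leaf(ptree, leaf_b)
    if leaf_a == leaf_b:
        return 0.0
    if ptree._pdm is None:
        ptree._pdm = ptree.tree.phylogenetic_distance_matrix()
    return float(ptree._pdm.patristic_distance(a.taxon, b.taxon))


def heatmap_order(ptree: PhyloTree) -> list[str]:
    """Leaves in display order: the reference leaf's side of every split first.

    Depth-first traversal preserving written child order, except that on the
    path from the root to the reference leaf the reference-containing child
    is visited first.  Deterministic for a given tree; with no reference set
    it is the plain written leaf order.
    """
    ref = ptree.reference

    def leaves_under(node):
        return [lf.taxon.label for lf in node.leaf_iter()]

    def walk(node) -> list[str]:
        if node.is_leaf():
            return [node.taxon.label]
        children = list(node.child_nodes())
        if ref is not None:
            children.sort(key=lambda c: 0 if ref in leaves_under(c) else 1)
        out: list[str] = []
        for child in children:
            out.extend(walk(child))
        return out

    return walk(ptree.tree.seed_node)
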