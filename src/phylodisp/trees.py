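"""Dated-tree handling on top of dendropy.

A :class:`DatedTree` wraps a rooted ``dendropy.Tree`` whose branch lengths
are in million years (my).  Trees are expected to be ultrametric within a
relative tolerance of 1e-6 of the root age; deviations beyond that are
flagged (``tree.ultrametric`` is False and a warning is emitted on read)
but not fatal, since empirical chronograms routinely carry rounding noise.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from phylodisp.errors import ValidationError

ULTRAMETRIC_RTOL = 1e-6


class DatedTree:
    """Rooted, dated phylogeny with tips labelled by taxa.

    Node ages are measured back from the present (tips at age ~0); the root
    age equals the maximum root-to-tip path length.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.tree.is_rooted = True  # dated chronograms are rooted by definition
        self._check_lengths()
        self._depths: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                self._depths[node] = 0.0
            else:
                self._depths[node] = self._depths[node.parent_node] + node.edge.length
        tip_depths = [self._depths[leaf] for leaf in tree.leaf_node_iter()]
        self.root_age: float = float(max(tip_depths))
        spread = max(tip_depths) - min(tip_depths)
        self.ultrametric: bool = spread <= ULTRAMETRIC_RTOL * max(self.root_age, 1.0)

    def _check_lengths(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                raise ValidationError("tree has an edge without a branch length")
            if edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")

    # -- structure ---------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def age_of(self, node: dendropy.Node) -> float:
        """Age of a node in my before present."""
        return self.root_age - self._depths[node]

    def mrca(self, labels: list[str]) -> dendropy.Node:
        taxa = [self.tree.taxon_namespace.get_taxon(l) for l in labels]
        missing = [l for l, t in zip(labels, taxa) if t is None]
        if missing:
            raise ValidationError(f"labels not on tree: {missing}")
        if len(taxa) == 1:
            (leaf,) = [l for l in self.tree.leaf_node_iter() if l.taxon is taxa[0]]
            return leaf
        return self.tree.mrca(taxa=taxa)

    def is_monophyletic(self, labels: list[str]) -> bool:
        node = self.mrca(labels)
        under = {l.taxon.label for l in node.leaf_iter()}
        return under == set(labels)

    def patristic_matrix(self) -> pd.DataFrame:
        """Symmetric tip-to-tip path-length matrix, labelled by taxa."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = sorted(self.tip_labels)
        taxa = {t.label: t for t in self.tree.taxon_namespace if t.label in set(labels)}
        n = len(labels)
        out = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
                out[i, j] = out[j, i] = d
        return pd.DataFrame(out, index=labels, columns=labels)

    # -- editing -----------------------------------------------------------

    def bifurcating(self) -> "DatedTree":
        """Copy with polytomies resolved to zero-length branches.

        Resolution order is deterministic: children are taken in sorted
        order of their smallest descendant tip label, and ladderized
        left-to-right, so repeated runs give identical contrast vectors.
        """
        tree = self.tree.clone(depth=1)
        for node in tree.postorder_node_iter():
            kids = node.child_nodes()
            if len(kids) <= 2:
                continue
            kids = sorted(kids, key=lambda n: min(l.taxon.label for l in n.leaf_iter()))
            while len(kids) > 2:
                a = kids.pop(0)
                b = kids.pop(0)
                joint = dendropy.Node()
                joint.edge.length = 0.0
                for child in (a, b):
                    node.remove_child(child)
                    joint.add_child(child)
                node.add_child(joint)
                kids.insert(0, joint)
        return DatedTree(tree)

    def extract(self, labels: list[str]) -> "DatedTree":
        """Subtree induced by ``labels``; path lengths among retained tips
        are preserved (suppressed unifurcations merge branch lengths)."""
        sub = self.tree.extract_tree_with_taxa_labels(labels)
        return DatedTree(sub)

    # -- I/O ---------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        self.tree.write(
            path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True
        )

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    @classmethod
    def from_newick(cls, text: str) -> "DatedTree":
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        return cls(tree)


def read_newick(path: str | Path) -> DatedTree:
    """Parse a Newick file into a :class:`DatedTree`.

    Missing branch lengths are an error; a non-ultrametric tree beyond the
    tolerance yields a warning and ``tree.ultrametric == False``.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    dated = DatedTree(tree)
    if not dated.ultrametric:
        warnings.warn(f"{path}: tree is not ultrametric within tolerance")
    return dated


def prune_to_tribes(tree: DatedTree, genus_to_tribe: dict[str, str | None]) -> DatedTree:
    """Prune a genus-level tree to one representative tip per tribe.

    Each tribe must be monophyletic on the tree; the representative is the
    alphabetically first member tip, relabelled by the tribe name.  Branch
    lengths along retained paths are preserved, so patristic distances
    among tribes are those of the original tree.  Tips that map to no tribe
    (orphans) are dropped.
    """
    tip_set = set(tree.tip_labels)
    tribe_tips: dict[str, list[str]] = {}
    for genus, tribe in genus_to_tribe.items():
        if tribe is not None and genus in tip_set:
            tribe_tips.setdefault(tribe, []).append(genus)
    if not tribe_tips:
        raise ValidationError("no tree tips map to any tribe")
    offenders = {}
    for tribe, tips in tribe_tips.items():
        if len(tips) > 1 and not tree.is_monophyletic(tips):
            node = tree.mrca(tips)
            under = sorted(l.taxon.label for l in node.leaf_iter())
            offenders[tribe] = sorted(set(under) - set(tips))
    if offenders:
        raise ValidationError(f"non-monophyletic tribes (intruding tips): {offenders}")
    reps = {tribe: min(tips) for tribe, tips in tribe_tips.items()}
    pruned = tree.extract(sorted(reps.values()))
    rep_to_tribe = {rep: tribe for tribe, rep in reps.items()}
    for leaf in pruned.tree.leaf_node_iter():
        leaf.taxon = dendropy.Taxon(label=rep_to_tribe[leaf.taxon.label])
    pruned.tree.update_taxon_namespace()
    return DatedTree(pruned.tree)
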