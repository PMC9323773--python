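"""Time-calibrated species trees: MRCA lookup and node ages in MYA.

Wraps a dendropy rooted tree whose branch lengths are in million years.
The tree must be ultrametric (all leaves at distance ~0 from the present);
a node's age is its distance to any descendant leaf, so the root age is
the oldest split and leaves sit at age 0.
"""

from __future__ import annotations

from pathlib import Path

import dendropy

from .io import data_path

ULTRAMETRIC_TOL = 1e-6

#: six-leaf fixture with hominoid / Old World monkey split depths (MYA)
DEFAULT_TREE_FILE = "primate6.nwk"


class SpeciesTreeError(ValueError):
    pass


class TimedSpeciesTree:
    """Rooted ultrametric species tree with node ages in million years."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._ages: dict[int, float] = {}
        self._labels: dict[int, str] = {}
        n_internal = 0
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._ages[id(node)] = 0.0
                self._labels[id(node)] = node.taxon.label
            else:
                child_ages = [self._ages[id(c)] + (c.edge.length or 0.0)
                              for c in node.child_nodes()]
                if max(child_ages) - min(child_ages) > ULTRAMETRIC_TOL:
                    raise SpeciesTreeError(
                        f"tree not ultrametric at an internal node: {child_ages}")
                self._ages[id(node)] = child_ages[0]
                label = node.label or f"node{n_internal}"
                node.label = label
                self._labels[id(node)] = label
                n_internal += 1
        for node in tree.preorder_node_iter():
            if not node.is_leaf():
                for c in node.child_nodes():
                    if (c.edge.length or 0.0) <= 0:
                        raise SpeciesTreeError("non-positive branch length")

    @classmethod
    def from_newick(cls, source: str | Path) -> "TimedSpeciesTree":
        path = Path(source)
        try:
            is_file = path.exists()
        except OSError:  # e.g. a newick string too long for a filename
            is_file = False
        if is_file:
            tree = dendropy.Tree.get(path=str(path), schema="newick",
                                     rooting="force-rooted",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(data=str(source), schema="newick",
                                     rooting="force-rooted",
                                     preserve_underscores=True)
        return cls(tree)

    @classmethod
    def default_fixture(cls) -> "TimedSpeciesTree":
        return cls.from_newick(data_path(DEFAULT_TREE_FILE))

    @property
    def leaves(self) -> list[str]:
        return [t.label for t in self._tree.taxon_namespace]

    @property
    def root_age(self) -> float:
        return self._ages[id(self._tree.seed_node)]

    def node_label(self, node) -> str:
        return self._labels[id(node)]

    def node_age(self, label: str) -> float:
        for node in self._tree.preorder_node_iter():
            if self._labels[id(node)] == label:
                return self._ages[id(node)]
        raise SpeciesTreeError(f"unknown node label: {label}")

    def mrca(self, species) -> tuple[str, float]:
        """(node label, age in MYA) of the MRCA of a species set."""
        species = sorted(set(species))
        known = {t.label for t in self._tree.taxon_namespace}
        for sp in species:
            if sp not in known:
                raise SpeciesTreeError(f"unknown species label: {sp}")
        if len(species) == 1:
            return species[0], 0.0
        node = self._tree.mrca(taxon_labels=species)
        return self._labels[id(node)], self._ages[id(node)]

    def leaf_set(self, node_label: str) -> frozenset[str]:
        """Species descending from the named node."""
        for node in self._tree.preorder_node_iter():
            if self._labels[id(node)] == node_label:
                return frozenset(lf.taxon.label for lf in node.leaf_iter())
        raise SpeciesTreeError(f"unknown node label: {node_label}")

    def internal_nodes(self) -> list[tuple[str, float]]:
        """(label, age) of every internal node, preorder."""
        return [(self._labels[id(n)], self._ages[id(n)])
                for n in self._tree.preorder_node_iter() if not n.is_leaf()]

    def preorder_edges(self):
        """(parent label or None, node label, branch length, is_leaf) preorder."""
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            yield (self._labels[id(parent)] if parent else None,
                   self._labels[id(node)],
                   node.edge.length or 0.0,
                   node.is_leaf())

    def pairwise_divergence(self, a: str, b: str) -> float:
        """Age of the split between two species (MYA)."""
        return self.mrca([a, b])[1]
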