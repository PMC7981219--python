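"""Rooted phylogeny container backed by dendropy.

Provides the quantities the comparative machinery needs: tip labels, node
depths, the Brownian-motion variance–covariance matrix C (shared root-to-MRCA
path lengths), and the patristic distance matrix.
"""
from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

from .utils import ValidationError


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labeled tips."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        self._tip_labels = sorted(labels)
        self._vcv_cache: np.ndarray | None = None
        self._depth_cache: dict | None = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).is_file()):
            text = Path(source).read_text()
        else:
            text = str(source)
        try:
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     preserve_underscores=True,
                                     suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several parse error types
            raise ValidationError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True,
                                    unquoted_underscores=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- basic structure ---------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in sorted order (the canonical ordering for matrices)."""
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def node_depths(self) -> dict:
        """Distance from the root to every node (root depth 0)."""
        if self._depth_cache is None:
            depths = {}
            root = self._tree.seed_node
            depths[id(root)] = 0.0
            for node in self._tree.preorder_node_iter():
                if node is root:
                    continue
                bl = node.edge.length if node.edge.length is not None else 0.0
                if bl < 0:
                    raise ValidationError("negative branch length")
                depths[id(node)] = depths[id(node.parent_node)] + bl
            self._depth_cache = depths
        return self._depth_cache

    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        depths = self.node_depths()
        return max(depths[id(l)] for l in self._tree.leaf_node_iter())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self.node_depths()
        tip_d = [depths[id(l)] for l in self._tree.leaf_node_iter()]
        return max(tip_d) - min(tip_d) <= tol * max(1.0, max(tip_d))

    # -- matrices ----------------------------------------------------------
    def vcv(self) -> np.ndarray:
        """BM covariance structure: C[i, j] = root-to-MRCA path length.

        Rows/columns follow ``tip_labels`` order.
        """
        if self._vcv_cache is None:
            n = self.n_tips
            idx = {lab: i for i, lab in enumerate(self._tip_labels)}
            depths = self.node_depths()
            C = np.zeros((n, n))
            # postorder: at each internal node, tip pairs split across child
            # subtrees have that node as their MRCA
            tipsets: dict = {}
            for node in self._tree.postorder_node_iter():
                if node.is_leaf():
                    i = idx[node.taxon.label]
                    C[i, i] = depths[id(node)]
                    tipsets[id(node)] = np.array([i])
                else:
                    child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
                    d = depths[id(node)]
                    for a in range(len(child_sets)):
                        for b in range(a + 1, len(child_sets)):
                            C[np.ix_(child_sets[a], child_sets[b])] = d
                            C[np.ix_(child_sets[b], child_sets[a])] = d
                    tipsets[id(node)] = np.concatenate(child_sets)
            self._vcv_cache = C
        return self._vcv_cache

    def patristic_matrix(self) -> np.ndarray:
        """Symmetric patristic (branch-length path) distance matrix, tip_labels order."""
        C = self.vcv()
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C

    def trait_vector(self, traits: dict) -> np.ndarray:
        """Trait values aligned to tip_labels order; errors list missing tips."""
        missing = [t for t in self._tip_labels if t not in traits]
        if missing:
            raise ValidationError(f"traits missing for tips: {missing}")
        return np.array([float(traits[t]) for t in self._tip_labels])
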