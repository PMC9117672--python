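"""Dated ultrametric phylogenies: reading, validation, and interrogation.

Trees are rooted, strictly bifurcating, with branch lengths in Ma. The shared
time axis runs backward from the present: tips sit at age 0 and node ages are
expressed in Ma BP (million years before present). dendropy does the Newick
parsing; this module adds the validation and the derived quantities used by
the diversification and biogeographic-assembly likelihoods (branching times,
lineages-through-time, sister pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "TreeValidationError",
    "SisterPair",
    "PostorderArrays",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "branching_times",
    "ltt",
    "cherries",
]

DEFAULT_ULTRAMETRIC_TOL = 1e-6


class TreeValidationError(ValueError):
    """Raised when a tree fails the dated-ultrametric contract."""


@dataclass(frozen=True)
class SisterPair:
    """A cherry: two tips whose MRCA has no other descendants."""

    a: str
    b: str
    age: float  # Ma BP of the pair's MRCA


@dataclass
class PostorderArrays:
    """Flat postorder encoding of a tree for the compiled pruning kernels.

    Nodes are indexed in postorder (children before parents, root last).
    ``left``/``right`` are -1 for tips; ``parent_age`` is the age of the
    node's parent (undefined, set to age, for the root).
    """

    age: np.ndarray
    left: np.ndarray
    right: np.ndarray
    parent_age: np.ndarray
    tip_index: np.ndarray  # position of each node among tips, -1 for internals
    tip_labels: list[str]


class Tree:
    """A validated, dated, ultrametric, strictly bifurcating phylogeny."""

    def __init__(self, dtree: dendropy.Tree, *, tol: float = DEFAULT_ULTRAMETRIC_TOL):
        self._dtree = dtree
        self._tol = tol
        self._validate_and_date()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, *, tol: float = DEFAULT_ULTRAMETRIC_TOL) -> "Tree":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick",
                                      suppress_internal_node_taxa=True,
                                      preserve_underscores=True)
        except Exception as exc:  # dendropy raises several parse errors
            raise TreeValidationError(f"Newick parse failure: {exc}") from exc
        return cls(dtree, tol=tol)

    # -- validation ----------------------------------------------------

    def _validate_and_date(self) -> None:
        dtree = self._dtree
        leaves = dtree.leaf_nodes()
        if len(leaves) < 2:
            raise TreeValidationError("tree must have at least two tips")
        labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
        if any(lb is None for lb in labels):
            raise TreeValidationError("every tip needs a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for node in dtree.preorder_node_iter():
            nch = len(node.child_nodes())
            if nch not in (0, 2):
                raise TreeValidationError(
                    f"tree is not strictly bifurcating (node with {nch} children)")
            if node.parent_node is not None:
                if node.edge.length is None:
                    raise TreeValidationError("missing branch length")
                if node.edge.length < 0:
                    raise TreeValidationError("negative branch length")

        # depths from the root; ultrametricity within absolute tolerance
        depth = {dtree.seed_node: 0.0}
        for node in dtree.preorder_node_iter():
            if node.parent_node is not None:
                depth[node] = depth[node.parent_node] + node.edge.length
        tip_depths = np.array([depth[lf] for lf in leaves])
        if tip_depths.max() - tip_depths.min() > self._tol:
            raise TreeValidationError(
                "tree is not ultrametric within tolerance "
                f"{self._tol:g} (tip depth spread {tip_depths.max() - tip_depths.min():g})")

        # ages in Ma BP; tips snapped to exactly 0
        height = float(tip_depths.mean())
        self._age = {}
        for node in dtree.preorder_node_iter():
            if node.is_leaf():
                self._age[node] = 0.0
            else:
                self._age[node] = max(height - depth[node], 0.0)
        self.tip_labels = sorted(labels)
        self.n_tips = len(labels)
        self.crown_age = self._age[dtree.seed_node]

    # -- derived quantities -------------------------------------------

    def branching_times(self) -> np.ndarray:
        """Ages of the internal nodes, Ma BP, descending (crown age first)."""
        if not hasattr(self, "_bt"):
            ages = sorted(
                (self._age[n] for n in self._dtree.preorder_internal_node_iter()),
                reverse=True)
            self._bt = np.asarray(ages, dtype=float)
        return self._bt

    def ltt(self) -> np.ndarray:
        """Lineage-through-time step series, rows of (age Ma BP, count).

        Starts at (crown age, 2) and ends at (0, n_tips); the count at age a
        equals 1 + the number of branching times older than a.
        """
        bt = self.branching_times()
        rows = [(bt[0], 2)]
        for i, age in enumerate(bt[1:], start=2):
            rows.append((age, i + 1))
        rows.append((0.0, self.n_tips))
        return np.asarray(rows, dtype=float)

    def cherries(self) -> list[SisterPair]:
        """All sister-species pairs (disjoint by construction)."""
        pairs = []
        for node in self._dtree.preorder_internal_node_iter():
            ch = node.child_nodes()
            if all(c.is_leaf() for c in ch):
                a, b = sorted(c.taxon.label for c in ch)
                pairs.append(SisterPair(a=a, b=b, age=self._age[node]))
        return pairs

    def prune_to(self, keep: list[str]) -> "Tree":
        """Prune to an explicit keep-list of tip labels (one tip per species)."""
        missing = sorted(set(keep) - set(self.tip_labels))
        if missing:
            raise TreeValidationError(f"keep-list labels not in tree: {missing}")
        dtree = self._dtree.clone(depth=1)
        taxa = [t for t in dtree.taxon_namespace if t.label in set(keep)]
        dtree.retain_taxa(taxa)
        return Tree(dtree, tol=self._tol)

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        s = self._dtree.as_string(schema="newick", suppress_rooting=True,
                                  unquoted_underscores=True)
        return s.strip() + ("" if s.strip().endswith(";") else ";")

    # -- kernel encoding ----------------------------------------------

    def postorder_arrays(self) -> PostorderArrays:
        if hasattr(self, "_post"):
            return self._post
        nodes = list(self._dtree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        age = np.zeros(n)
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        parent_age = np.zeros(n)
        tip_index = np.full(n, -1, dtype=np.int64)
        tip_labels: list[str] = []
        for i, node in enumerate(nodes):
            age[i] = self._age[node]
            ch = node.child_nodes()
            if ch:
                left[i], right[i] = index[id(ch[0])], index[id(ch[1])]
            else:
                tip_index[i] = len(tip_labels)
                tip_labels.append(node.taxon.label)
            parent_age[i] = (self._age[node.parent_node]
                             if node.parent_node is not None else age[i])
        self._post = PostorderArrays(age=age, left=left, right=right,
                                     parent_age=parent_age, tip_index=tip_index,
                                     tip_labels=tip_labels)
        return self._post

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_tips={self.n_tips}, crown_age={self.crown_age:.4g} Ma)"


def read_newick(path, *, tol: float = DEFAULT_ULTRAMETRIC_TOL) -> Tree:
    """Read and validate a single dated tree from a Newick file."""
    with open(path) as fh:
        return Tree.from_newick(fh.read(), tol=tol)


def read_newick_list(path, *, tol: float = DEFAULT_ULTRAMETRIC_TOL) -> list[Tree]:
    """Read a multi-tree Newick file (one tree per line), e.g. posterior draws."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(Tree.from_newick(line, tol=tol))
    return trees


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def branching_times(tree: Tree) -> np.ndarray:
    return tree.branching_times()


def ltt(tree: Tree) -> np.ndarray:
    return tree.ltt()


def cherries(tree: Tree) -> list[SisterPair]:
    return tree.cherries()
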