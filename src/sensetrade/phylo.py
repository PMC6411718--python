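"""Rooted phylogenies, Brownian covariance matrices, and trait/tree alignment.

The tree container wraps a dendropy tree and exposes exactly what the
comparative machinery needs: a stable tip order, Newick round-tripping, the
Brownian variance-covariance matrix V (V[i,j] = shared root-to-tip path
length), and strict, reported pruning to a set of species labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .exceptions import AlignmentError, NewickParseError

__all__ = ["Phylogeny", "PhyloCov", "read_newick", "write_newick",
           "vcv_from_tree", "lambda_transform", "align_traits_to_tree"]


@dataclass(frozen=True)
class PhyloCov:
    """Brownian shared-path covariance matrix with its tip order."""

    matrix: np.ndarray
    tip_order: tuple

    def __post_init__(self) -> None:
        V = np.asarray(self.matrix, dtype=float)
        n = len(self.tip_order)
        if V.shape != (n, n):
            raise ValueError("covariance matrix shape does not match tip order")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        object.__setattr__(self, "matrix", V)

    @property
    def n(self) -> int:
        return len(self.tip_order)


class Phylogeny:
    """A rooted tree with branch lengths and >= 2 uniquely labelled tips."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label if leaf.taxon else None
                  for leaf in tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise NewickParseError("every tip must be labelled")
        if len(labels) < 2:
            raise NewickParseError("a phylogeny needs at least 2 tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise NewickParseError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise NewickParseError(
                    f"missing branch length above node {edge.head_node!r}")
            if edge.length < 0:
                raise NewickParseError(f"negative branch length {edge.length}")
        self._tips = tuple(sorted(labels))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        if ";" not in text:
            raise NewickParseError("Newick string must end with ';'")
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(str(exc)) from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # -- basic queries -------------------------------------------------------

    @property
    def tips(self) -> tuple:
        """Tip labels in canonical (sorted) order."""
        return self._tips

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def depths(self) -> pd.Series:
        """Root-to-tip distance per tip."""
        d = {}
        for leaf in self._tree.leaf_node_iter():
            d[leaf.taxon.label] = leaf.distance_from_root()
        return pd.Series(d).loc[list(self._tips)]

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        d = self.depths().to_numpy()
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-10))

    # -- covariance ---------------------------------------------------------

    def vcv(self) -> PhyloCov:
        """Brownian covariance: V[i,j] = branch length shared by tips i and j.

        Computed by one preorder pass, adding each edge's length to every
        pair of tips in the clade below it.
        """
        idx = {lab: i for i, lab in enumerate(self._tips)}
        n = len(self._tips)
        V = np.zeros((n, n))
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                node._tip_idx = np.array([idx[node.taxon.label]])
            else:
                node._tip_idx = np.concatenate([c._tip_idx for c in node.child_nodes()])
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node or edge.length is None:
                continue
            below = edge.head_node._tip_idx
            V[np.ix_(below, below)] += edge.length
        return PhyloCov(matrix=V, tip_order=self._tips)

    # -- pruning ------------------------------------------------------------

    def prune_to(self, labels) -> "Phylogeny":
        """Return a new tree restricted to `labels` (must all be tips)."""
        keep = set(labels)
        missing = keep - set(self._tips)
        if missing:
            raise AlignmentError(f"labels not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise AlignmentError("cannot prune below 2 tips")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(keep)
        return Phylogeny(clone)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny."""
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def vcv_from_tree(tree: Phylogeny) -> PhyloCov:
    return tree.vcv()


def lambda_transform(V: PhyloCov, lam: float) -> PhyloCov:
    """Pagel's λ transform: multiply off-diagonal covariances by λ.

    λ = 1 leaves the Brownian structure intact; λ = 0 removes all shared
    history (a star phylogeny with the original tip depths).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    W = lam * V.matrix
    np.fill_diagonal(W, np.diag(V.matrix))
    return PhyloCov(matrix=W, tip_order=V.tip_order)


@dataclass
class AlignmentReport:
    """What was dropped while matching a trait table against a tree."""

    kept: tuple
    dropped_from_tree: tuple = ()
    dropped_from_table: tuple = ()

    def __str__(self) -> str:
        parts = [f"{len(self.kept)} species aligned"]
        if self.dropped_from_tree:
            parts.append(f"pruned from tree: {', '.join(self.dropped_from_tree)}")
        if self.dropped_from_table:
            parts.append(f"unused table rows: {', '.join(self.dropped_from_table)}")
        return "; ".join(parts)


def align_traits_to_tree(traits, tree: Phylogeny):
    """Match trait labels to tree tips, pruning both sides explicitly.

    `traits` is a Series (one trait) or DataFrame (several, indexed by
    species).  Matching is strict and case-sensitive; species present on
    one side only are dropped and reported, never silently.  Returns
    ``(pruned_tree, aligned_traits, report)`` with trait rows reordered to
    the pruned tree's tip order.
    """
    if isinstance(traits, pd.DataFrame):
        labels = traits.index
    elif isinstance(traits, pd.Series):
        labels = traits.index
    else:
        raise TypeError("traits must be a pandas Series or DataFrame")
    if labels.has_duplicates:
        raise AlignmentError(f"duplicate species labels in traits: "
                             f"{sorted(labels[labels.duplicated()].unique())}")
    tip_set = set(tree.tips)
    label_set = set(labels)
    common = tip_set & label_set
    # a case-insensitive hit among the unmatched labels means a labelling
    # bug, not genuinely disjoint data: refuse rather than silently drop
    folded = ({str(t).lower() for t in tip_set - common}
              & {str(l).lower() for l in label_set - common})
    if folded:
        raise AlignmentError(
            f"labels differing only by case between traits and tree: "
            f"{sorted(folded)}; matching is case-sensitive")
    if not common:
        raise AlignmentError("no species shared between traits and tree")
    pruned = tree.prune_to(common) if common != tip_set else tree
    report = AlignmentReport(
        kept=tuple(pruned.tips),
        dropped_from_tree=tuple(sorted(tip_set - common)),
        dropped_from_table=tuple(sorted(label_set - common)),
    )
    aligned = traits.loc[list(pruned.tips)]
    if isinstance(aligned, pd.DataFrame):
        if aligned.isna().any().any():
            raise AlignmentError("missing trait values after alignment")
    elif aligned.isna().any():
        raise AlignmentError("missing trait values after alignment")
    return pruned, aligned, report
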