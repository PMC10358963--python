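"""Rooted phylogenies: Newick I/O, phylogenetic covariance, polytomy
resolution and taxon-subset pruning.

The tree is the scaffold onto which growth traits are mapped.  All
phylogenetic-signal computations downstream consume the phylogenetic
variance-covariance matrix ``C`` built here: ``C[i, j]`` is the shared
root-to-MRCA path length of tips *i* and *j* (the expected trait covariance
under Brownian motion, up to the rate constant), and the diagonal holds
root-to-tip distances.

Branch lengths are treated as given and unitless; trees are used as rooted
as written, with no re-rooting.
"""
from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "load_taxonomy",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass(frozen=True)
class PhyloCovariance:
    """Phylogenetic variance-covariance matrix in a fixed tip order."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


class Phylogeny:
    """A rooted tree with non-negative branch lengths and unique tip labels.

    Wraps a :class:`dendropy.Tree`; the wrapper owns validation, the
    covariance computation, and the small set of manipulations the trait
    analyses need (polytomy resolution, subtree extraction).

    Parameters
    ----------
    tree:
        A rooted dendropy tree. The root's own edge length, if any, is
        ignored; every other edge must carry a non-negative length.
    tip_annotations:
        Optional per-tip metadata, e.g. ``{"iso1": {"class": "Sordariomycetes",
        "order": "Xylariales"}}``.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        tip_annotations: Mapping[str, Mapping[str, str]] | None = None,
    ) -> None:
        self._tree = tree
        self.tip_annotations: dict[str, dict[str, str]] = {
            k: dict(v) for k, v in (tip_annotations or {}).items()
        }
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        source: str,
        *,
        is_path: bool = True,
        assume_length: float | None = None,
        tip_annotations: Mapping[str, Mapping[str, str]] | None = None,
    ) -> "Phylogeny":
        """Parse a single rooted Newick tree.

        Edges without a branch length are rejected unless ``assume_length``
        supplies a constant to substitute (a silent default would corrupt
        the covariance matrix). The root edge is exempt and treated as 0.
        """
        kwargs = dict(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
        try:
            if is_path:
                tree = dendropy.Tree.get(path=source, **kwargs)
            else:
                tree = dendropy.Tree.get(data=source, **kwargs)
        except Exception as exc:  # dendropy raises several error types
            if "duplicate" in str(exc).lower():
                raise TreeValidationError(
                    f"duplicate tip labels: {exc}"
                ) from exc
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        root = tree.seed_node
        if root.edge.length is None:
            root.edge.length = 0.0
        missing = [e for e in tree.preorder_edge_iter()
                   if e.head_node is not root and e.length is None]
        if missing:
            if assume_length is None:
                raise TreeValidationError(
                    f"{len(missing)} edge(s) lack branch lengths; pass "
                    "assume_length to substitute a constant"
                )
            for e in missing:
                e.length = float(assume_length)
        return cls(tree, tip_annotations=tip_annotations)

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick())

    def as_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip() + "\n"

    # -- basic structure --------------------------------------------------

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeValidationError("tree contains an unlabeled tip")
            labels.append(leaf.taxon.label)
        seen: set[str] = set()
        dups = {l for l in labels if l in seen or seen.add(l)}
        if dups:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dups)}")
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is not None and edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {edge.length}"
                )
        self._tips = tuple(labels)

    @property
    def tips(self) -> tuple[str, ...]:
        """Tip labels in the tree's stable leaf iteration order."""
        return self._tips

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            self._tree.clone(depth=1), tip_annotations=self.tip_annotations
        )

    # -- covariance -------------------------------------------------------

    def vcv(self) -> PhyloCovariance:
        """Phylogenetic variance-covariance matrix.

        ``C[i, j]`` is the root-to-MRCA path length shared by tips *i* and
        *j*; the diagonal is the root-to-tip distance. Requires >= 2 tips.
        """
        labels = self.tips
        if len(labels) < 2:
            raise TreeValidationError("covariance needs >= 2 tips")
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        depth: dict[int, float] = {}
        below: dict[int, list[int]] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depth[id(node)] = 0.0
            else:
                depth[id(node)] = depth[id(node.parent_node)] + (
                    node.edge.length or 0.0
                )
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label]
                C[i, i] = depth[id(node)]
                below[id(node)] = [i]
            else:
                groups = [below.pop(id(c)) for c in node.child_nodes()]
                d = depth[id(node)]
                for gi in range(len(groups)):
                    for gj in range(gi + 1, len(groups)):
                        for a in groups[gi]:
                            for b in groups[gj]:
                                C[a, b] = C[b, a] = d
                below[id(node)] = [x for g in groups for x in g]
        return PhyloCovariance(labels=labels, matrix=C)

    def patristic_matrix(self) -> pd.DataFrame:
        """All-pairs tip-to-tip path lengths, derived from the covariance."""
        cov = self.vcv()
        d = np.diag(cov.matrix)
        D = d[:, None] + d[None, :] - 2 * cov.matrix
        np.fill_diagonal(D, 0.0)
        return pd.DataFrame(D, index=cov.labels, columns=cov.labels)

    # -- manipulation -----------------------------------------------------

    def resolve_polytomies(self, seed: int) -> "Phylogeny":
        """Randomly break every multichotomy into dichotomies.

        Inserted edges have length 0, so the covariance matrix and all
        patristic distances are unchanged. Deterministic given ``seed``;
        an already-binary tree is returned unchanged (as a copy).
        """
        tree = self._tree.clone(depth=1)
        tree.resolve_polytomies(rng=random.Random(seed))
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                edge.length = 0.0
        return Phylogeny(tree, tip_annotations=self.tip_annotations)

    def subtree(self, keep: Iterable[str]) -> "Phylogeny":
        """Prune to exactly the tips in ``keep``.

        Suppresses unary nodes by summing their incident edge lengths, so
        patristic distances among retained tips are preserved.
        """
        keep = set(keep)
        missing = keep - set(self.tips)
        if missing:
            raise TreeValidationError(
                f"labels not in tree: {sorted(missing)}"
            )
        if len(keep) < 2:
            raise TreeValidationError("subtree needs >= 2 tips")
        tree = self._tree.extract_tree_with_taxa_labels(labels=keep)
        annotations = {
            k: v for k, v in self.tip_annotations.items() if k in keep
        }
        return Phylogeny(tree, tip_annotations=annotations)

    def restrict_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Subtree of tips shared with ``labels``, logging how many drop.

        Matching is exact, case-sensitive string equality.
        """
        shared = [t for t in self.tips if t in set(labels)]
        dropped = self.n_tips - len(shared)
        if dropped:
            logger.info("dropping %d tip(s) absent from trait table", dropped)
        return self.subtree(shared) if dropped else self.copy()

    def annotate_tips(self, table: pd.DataFrame) -> None:
        """Attach taxonomy columns (indexed by isolate id) to matching tips."""
        for tip in self.tips:
            if tip in table.index:
                self.tip_annotations[tip] = {
                    k: v for k, v in table.loc[tip].items() if pd.notna(v)
                }

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"


def read_newick(path: str, assume_length: float | None = None) -> Phylogeny:
    """Convenience wrapper: parse a Newick file into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(path, assume_length=assume_length)


def load_taxonomy(path: str) -> pd.DataFrame:
    """Read a tip-annotation sidecar CSV (isolate_id, otu_id, class, order)."""
    df = pd.read_csv(path, dtype=str)
    if "isolate_id" not in df.columns:
        raise ValueError("taxonomy CSV must have an isolate_id column")
    return df.set_index("isolate_id")
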