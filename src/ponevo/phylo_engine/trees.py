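"""Phylogenetic tree container used by the likelihood engine.

Trees are parsed from newick (via dendropy) into flat postorder arrays,
which is what the pruning recursion and the branch-length optimizer
consume.  Branches may carry a foreground mark, written in newick as a
``#1`` suffix on the leaf or internal-node label (the convention used by
codon-model software for branch-site tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["PhyloTree"]


@dataclass
class PhyloTree:
    """Rooted tree in postorder arrays (root is the last node).

    ``parent[i]`` is the parent index (-1 for root), ``lengths[i]`` the
    length of the branch above node ``i``, ``children[i]`` the child
    indices, ``labels[i]`` the leaf name (None for internal nodes) and
    ``foreground[i]`` whether the branch above ``i`` is marked.
    """

    parent: np.ndarray
    lengths: np.ndarray
    children: list[list[int]]
    labels: list[str | None]
    foreground: np.ndarray

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaf_indices(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    @property
    def leaf_names(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_indices]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.parent.copy(),
            self.lengths.copy(),
            [list(c) for c in self.children],
            list(self.labels),
            self.foreground.copy(),
        )

    def validate(self) -> None:
        if np.any(self.lengths[: self.root] < 0):
            raise ValueError("negative branch length")

    def total_length(self) -> float:
        return float(self.lengths[: self.root].sum())

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        index: dict[int, int] = {}
        parent, lengths, children, labels, fg = [], [], [], [], []
        for i, node in enumerate(dtree.postorder_node_iter()):
            index[id(node)] = i
            raw = node.taxon.label if node.taxon is not None else node.label
            mark = False
            if raw is not None and raw.endswith("#1"):
                mark = True
                raw = raw[:-2].strip() or None
            labels.append(raw if node.is_leaf() else None)
            if node.is_leaf() and labels[-1] is None:
                raise ValueError("leaf without a name")
            lengths.append(float(node.edge.length or 0.0))
            children.append([index[id(c)] for c in node.child_nodes()])
            parent.append(-1)
            fg.append(mark)
        for i, ch in enumerate(children):
            for c in ch:
                parent[c] = i
        tree = cls(
            np.asarray(parent),
            np.asarray(lengths, dtype=float),
            children,
            labels,
            np.asarray(fg, dtype=bool),
        )
        names = tree.leaf_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")
        tree.validate()
        return tree

    def to_newick(self) -> str:
        def render(i: int) -> str:
            mark = "#1" if self.foreground[i] else ""
            if not self.children[i]:
                return f"{self.labels[i]}{mark}:{self.lengths[i]:.10g}"
            inner = ",".join(render(c) for c in self.children[i])
            if i == self.root:
                return f"({inner}){mark}"
            return f"({inner}){mark}:{self.lengths[i]:.10g}"

        return render(self.root) + ";"

    # ------------------------------------------------------------------
    def resolved_binary(self) -> "PhyloTree":
        """Deterministically resolve multifurcations with zero-length nodes.

        Children are folded left-to-right in their stored order, so the
        resolution is reproducible for a given input newick.
        """
        # Build a nested structure, fold, then re-flatten via newick round-trip.
        def fold(i: int) -> str:
            if not self.children[i]:
                mark = "#1" if self.foreground[i] else ""
                return f"{self.labels[i]}{mark}:{self.lengths[i]:.10g}"
            parts = [fold(c) for c in self.children[i]]
            while len(parts) > 2:
                merged = f"({parts[0]},{parts[1]}):0"
                parts = [merged] + parts[2:]
            inner = ",".join(parts)
            mark = "#1" if self.foreground[i] else ""
            if i == self.root:
                return f"({inner}){mark}"
            return f"({inner}){mark}:{self.lengths[i]:.10g}"

        return PhyloTree.from_newick(fold(self.root) + ";")

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        t = self.copy()
        t.lengths = np.asarray(lengths, dtype=float).copy()
        return t
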