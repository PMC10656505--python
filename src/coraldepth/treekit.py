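"""Time-calibrated phylogeny container with branch rate scalars.

The central object is :class:`TimeTree`, a rooted tree stored in flat arrays
indexed by *post-order node ids*: iterating ids ``0..n_nodes-1`` always visits
children before parents, and the root is ``n_nodes - 1``.  This numbering is
stable across operations so posterior samples, trait reconstructions and
branch classifications indexed by node id line up without bookkeeping.

Every non-root node owns the branch above it; ``branch_id == node_id`` of the
node below the branch.  Branch lengths are in Ma.  Each branch additionally
carries a dimensionless rate scalar ``r`` (default 1) used by the
variable-rates machinery: the *scaled* length of a branch is ``length * r``.

Newick/NEXUS parsing is delegated to dendropy; serialization is done here so
that scalars can be written as ``[&r=...]`` comment tags that plain Newick
readers skip.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy


class TreeParseError(ValueError):
    """Raised when tree text cannot be parsed (message names the position)."""


@dataclass(frozen=True)
class PADPair:
    """A phylogenetic ancestor-descendant comparison: one per branch."""

    ancestor: int
    descendant: int
    branch_id: int


class TimeTree:
    """Rooted time tree in post-order flat-array form.

    Parameters
    ----------
    parent
        ``parent[i]`` is the node id of node *i*'s parent; ``-1`` for the root.
        Ids must already be in post-order (children before parents, root last).
    length
        Length (Ma) of the branch above each node; the root entry is 0.
    labels
        Per-node label; tips must be labelled, internal labels optional.
    scalar
        Branch rate scalar ``r`` per node (branch above the node); default 1.
    """

    def __init__(self, parent, length, labels, scalar=None):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if self.length.size != n or len(self.labels) != n:
            raise ValueError("parent/length/labels size mismatch")
        if scalar is None:
            self.scalar = np.ones(n)
        else:
            self.scalar = np.asarray(scalar, dtype=float).copy()
        self._validate()
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        self.n_nodes = n
        self.n_tips = int(self.is_tip.sum())
        self.root = n - 1
        self._tips_below: list[np.ndarray] | None = None

    # -- construction ----------------------------------------------------

    def _validate(self):
        n = self.parent.size
        if n == 0:
            raise ValueError("empty tree")
        if self.parent[n - 1] != -1:
            raise ValueError("root (last post-order id) must have parent -1")
        if np.sum(self.parent == -1) != 1:
            raise ValueError("tree must have exactly one root")
        if np.any(self.parent[: n - 1] <= np.arange(n - 1)):
            raise ValueError("ids are not in post-order (parent must be > child)")
        if np.any(self.length[: n - 1] < 0) or np.any(np.isnan(self.length[: n - 1])):
            raise ValueError("branch lengths must be finite and >= 0")
        if np.any(~(self.scalar > 0)):
            raise ValueError("branch scalars must be > 0")

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        order = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n)
        scalar = np.ones(n)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(order):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeParseError("branch without a length in input tree")
                length[i] = float(nd.edge.length)
                for c in nd.comments:
                    c = c.strip()
                    if c.startswith("&r="):
                        scalar[i] = float(c[3:])
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None:
                labels[i] = nd.label
        tree = cls(parent, length, labels, scalar)
        for i in range(n):
            if tree.is_tip[i] and labels[i] is None:
                raise TreeParseError("unlabelled tip in input tree")
        return tree

    @classmethod
    def read(cls, source: str, schema: str = "newick") -> "TimeTree":
        """Parse a tree from Newick/NEXUS text or a file path.

        ``source`` is treated as literal tree text if it contains ``(`` or
        ``#NEXUS``, otherwise as a path.
        """
        is_text = ("(" in source or source.rstrip().endswith(";")
                   or source.lstrip().upper().startswith("#NEXUS"))
        try:
            if is_text:
                dtree = dendropy.Tree.get(
                    data=source, schema=schema,
                    suppress_internal_node_taxa=True,
                    extract_comment_metadata=False,
                )
            else:
                dtree = dendropy.Tree.get(
                    path=source, schema=schema,
                    suppress_internal_node_taxa=True,
                    extract_comment_metadata=False,
                )
        except Exception as exc:  # dendropy raises several error types
            raise TreeParseError(f"could not parse tree ({schema}): {exc}") from exc
        return cls.from_dendropy(dtree)

    # -- serialization ---------------------------------------------------

    @staticmethod
    def _fmt(x: float) -> str:
        s = repr(float(x))
        return s[:-2] if s.endswith(".0") else s

    def to_newick(self, include_scalars: bool = True) -> str:
        """Serialize to Newick; non-unit scalars become ``[&r=...]`` tags."""
        out = io.StringIO()

        def write(i: int):
            if not self.is_tip[i]:
                out.write("(")
                for k, c in enumerate(self.children[i]):
                    if k:
                        out.write(",")
                    write(c)
                out.write(")")
            if self.labels[i] is not None:
                out.write(str(self.labels[i]))
            if self.parent[i] >= 0:
                out.write(":" + self._fmt(self.length[i]))
                if include_scalars and self.scalar[i] != 1.0:
                    out.write(f"[&r={self._fmt(self.scalar[i])}]")

        write(self.root)
        out.write(";")
        return out.getvalue()

    def write(self, path: str, schema: str = "newick", include_scalars: bool = True):
        text = self.to_newick(include_scalars=include_scalars)
        if schema == "nexus":
            dtree = dendropy.Tree.get(data=text, schema="newick",
                                      suppress_internal_node_taxa=True,
                                      extract_comment_metadata=False)
            text = dtree.as_string(schema="nexus")
        with open(path, "w") as fh:
            fh.write(text)

    # -- structure queries -----------------------------------------------

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children if c) and all(
            len(self.children[i]) == 2 for i in range(self.n_nodes) if not self.is_tip[i]
        )

    @property
    def tip_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    def preorder(self) -> np.ndarray:
        """Node ids root-first (reverse of the id ordering)."""
        return np.arange(self.n_nodes - 1, -1, -1)

    def depths_from_root(self, use_scalars: bool = False) -> np.ndarray:
        """Root-to-node path length (Ma, scaled by r if requested)."""
        ln = self.length * self.scalar if use_scalars else self.length
        d = np.zeros(self.n_nodes)
        for i in self.preorder():
            p = self.parent[i]
            if p >= 0:
                d[i] = d[p] + ln[i]
        return d

    def node_ages(self) -> np.ndarray:
        """Ma before present: root age minus root-to-node path length.

        Root age is the maximum root-to-tip distance, so tips of an
        ultrametric tree get age 0 and non-ultrametric trees are accepted.
        """
        d = self.depths_from_root()
        return d.max() - d

    def path_wise_distance(self, node_id: int, use_scalars: bool = False) -> float:
        """Sum of branch lengths (times r if ``use_scalars``) from root."""
        if not 0 <= node_id < self.n_nodes:
            raise KeyError(f"unknown node id {node_id}")
        total = 0.0
        i = node_id
        while self.parent[i] >= 0:
            ln = self.length[i]
            if use_scalars:
                ln *= self.scalar[i]
            total += ln
            i = self.parent[i]
        return total

    def clade_nodes(self, node_id: int) -> np.ndarray:
        """All node ids in the subtree rooted at ``node_id`` (inclusive)."""
        keep = np.zeros(self.n_nodes, dtype=bool)
        keep[node_id] = True
        for i in range(node_id - 1, -1, -1):
            if keep[self.parent[i]]:
                keep[i] = True
        return np.flatnonzero(keep)

    def tips_below(self) -> list[np.ndarray]:
        """Per node: indices *into the tip array* of tips in its subtree."""
        if self._tips_below is None:
            tip_index = {t: k for k, t in enumerate(self.tip_ids)}
            sets: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i in range(self.n_nodes):
                if self.is_tip[i]:
                    sets[i] = [tip_index[i]]
                else:
                    for c in self.children[i]:
                        sets[i].extend(sets[c])
            self._tips_below = [np.array(s, dtype=np.int64) for s in sets]
        return self._tips_below

    # -- PAD enumeration -------------------------------------------------

    def enumerate_pads(self) -> list[PADPair]:
        """One ancestor-descendant pair per branch; the root has none.

        For a binary tree with *n* tips this yields ``2n - 2`` pairs (1018 on
        a 510-tip tree).  A single-node tree yields no pairs (any root edge
        is ignored on input).
        """
        return [
            PADPair(ancestor=int(self.parent[i]), descendant=i, branch_id=i)
            for i in range(self.n_nodes - 1)
        ]

    # -- false tips ------------------------------------------------------

    def attach_false_tips(self) -> tuple["TimeTree", np.ndarray, dict[int, int]]:
        """Graft a zero-length pseudo-tip onto every internal node.

        Returns ``(augmented_tree, node_map, false_tip_of)`` where
        ``node_map[old_id] -> new_id`` for original nodes and
        ``false_tip_of[old_internal_id] -> new tip id`` for the grafted tips.
        The grafted tips are labelled ``FT<old_id>``.  Path-wise distances of
        original nodes are unchanged, and each false tip inherits the
        distance of its host node (zero-length branch).
        """
        children = [list(c) for c in self.children]
        n_old = self.n_nodes
        extra_host = []  # host old-id per false tip, in creation order
        for i in range(n_old):
            if not self.is_tip[i]:
                children[i].append(n_old + len(extra_host))
                extra_host.append(i)
        n_new = n_old + len(extra_host)

        order: list[int] = []

        def post(i: int):
            for c in children[i] if i < n_old else []:
                post(c)
            order.append(i)

        import sys
        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 10 * n_new + 100))
        try:
            post(self.root)
        finally:
            sys.setrecursionlimit(old_limit)
        new_id = {old: k for k, old in enumerate(order)}

        parent = np.full(n_new, -1, dtype=np.int64)
        length = np.zeros(n_new)
        scalar = np.ones(n_new)
        labels: list[str | None] = [None] * n_new
        for old in range(n_old):
            k = new_id[old]
            labels[k] = self.labels[old]
            if self.parent[old] >= 0:
                parent[k] = new_id[self.parent[old]]
                length[k] = self.length[old]
                scalar[k] = self.scalar[old]
        false_tip_of = {}
        for j, host in enumerate(extra_host):
            old = n_old + j
            k = new_id[old]
            parent[k] = new_id[host]
            length[k] = 0.0
            labels[k] = f"FT{host}"
            false_tip_of[host] = k
        node_map = np.array([new_id[i] for i in range(n_old)], dtype=np.int64)
        return TimeTree(parent, length, labels, scalar), node_map, false_tip_of

    # -- tables ----------------------------------------------------------

    def node_table(self) -> pd.DataFrame:
        """Per-node CSV-ready table: id, label, age (Ma), tip flag, scalar."""
        ages = self.node_ages()
        return pd.DataFrame(
            {
                "node_id": np.arange(self.n_nodes),
                "label": self.labels,
                "age_ma": ages,
                "is_tip": self.is_tip,
                "branch_length_ma": self.length,
                "scalar_r": self.scalar,
            }
        )

    def with_scalars(self, scalar: np.ndarray) -> "TimeTree":
        """Copy of the tree with a replaced per-branch scalar vector."""
        return TimeTree(self.parent, self.length, self.labels, scalar)

    def __repr__(self):
        return f"<TimeTree n_tips={self.n_tips} n_nodes={self.n_nodes}>"
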