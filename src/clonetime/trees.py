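"""Rooted tree container used across the pipeline.

Tips are single-cell-derived colonies; every non-root node carries the branch
that connects it to its parent.  Branch lengths are interpreted by context:
mutation counts ("molecular time") before calibration, years after.

The representation is a flat parent array (root has parent ``-1``) with tips
occupying node ids ``0 .. n_tips-1``.  Multifurcations are allowed — greedy
perfect-phylogeny construction and embryonic bursts both produce them.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["Tree"]


@dataclass
class Tree:
    parent: np.ndarray
    tip_names: list[str]
    lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths, dtype=float)
            if self.lengths.shape != self.parent.shape:
                raise ValueError("lengths and parent must have the same shape")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")

    # ------------------------------------------------------------------ basic
    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(v)
        return ch

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def postorder(self) -> list[int]:
        """Children before parents."""
        ch = self.children()
        out: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(ch[v])
        if len(out) != self.n_nodes:
            raise ValueError("malformed tree: not all nodes reachable from root")
        out.reverse()
        return out

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def copy(self) -> "Tree":
        return Tree(
            self.parent.copy(),
            list(self.tip_names),
            None if self.lengths is None else self.lengths.copy(),
        )

    # ------------------------------------------------------------- structure
    def tip_sets(self) -> np.ndarray:
        """Boolean matrix (n_nodes, n_tips): tips descending from each node.

        A node's own row includes itself if it is a tip; this doubles as the
        carrier-set matrix of the branch above the node.
        """
        m = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        for v in self.postorder():
            if self.is_tip(v):
                m[v, v] = True
            p = self.parent[v]
            if p >= 0:
                m[p] |= m[v]
        return m

    def mrca(self, tips: list[int]) -> int:
        if not tips:
            raise ValueError("mrca of an empty tip set")
        sets = self.tip_sets()
        want = np.zeros(self.n_tips, dtype=bool)
        want[list(tips)] = True
        best, best_size = self.root, self.n_tips + 1
        for v in range(self.n_nodes):
            sz = int(sets[v].sum())
            if sz < best_size and np.all(sets[v][want]):
                best, best_size = v, sz
        return best

    def node_depths(self) -> np.ndarray:
        """Cumulative branch length from the root to each node."""
        if self.lengths is None:
            raise ValueError("tree has no branch lengths")
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.lengths[v]
        return depth

    # ------------------------------------------------------------------- i/o
    def to_newick(self) -> str:
        ch = self.children()
        L = self.lengths if self.lengths is not None else np.zeros(self.n_nodes)

        def render(v: int) -> str:
            label = self.tip_names[v] if self.is_tip(v) else f"nd{v}"
            if ch[v]:
                inner = ",".join(render(c) for c in ch[v])
                body = f"({inner}){label}"
            else:
                body = label
            if self.parent[v] < 0:
                return body
            return f"{body}:{L[v]:.10g}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return render(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, source: str) -> "Tree":
        """Parse a Newick string (dendropy does the parsing).

        Tip order in the returned tree follows dendropy's leaf iteration
        order; internal ``nd*`` labels from :meth:`to_newick` are ignored.
        """
        dt = dendropy.Tree.get(data=source, schema="newick",
                               preserve_underscores=True)
        leaves = [lf for lf in dt.leaf_node_iter()]
        internals = [nd for nd in dt.preorder_node_iter() if not nd.is_leaf()]
        ids: dict = {}
        for i, lf in enumerate(leaves):
            ids[lf] = i
        for j, nd in enumerate(internals):
            ids[nd] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        for nd in dt.preorder_node_iter():
            if nd.parent_node is not None:
                parent[ids[nd]] = ids[nd.parent_node]
                lengths[ids[nd]] = nd.edge.length if nd.edge.length is not None else 0.0
        names = [lf.taxon.label if lf.taxon else "" for lf in leaves]
        return cls(parent, names, lengths)

    @classmethod
    def read_newick(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())
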