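"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately naive (exhaustive enumeration, direct pmf
evaluation) and independent of the implementation paths it checks.
"""

import itertools

import numpy as np

from clonetime.genotypes import MISSING
from clonetime.trees import Tree


def enumerate_rooted_trees(n_tips: int):
    """All rooted binary topologies on n labelled tips, as Tree objects.

    Built by stepwise tip insertion into every edge (including a new root
    edge), the classic (2k-3)!! construction on rooted trees.
    """
    # shapes are nested tuples over tip indices
    def insert(tree, tip):
        # returns all trees obtained by joining `tip` somewhere inside `tree`
        out = [(tree, tip)]
        if isinstance(tree, tuple):
            a, b = tree
            out += [(x, b) for x in insert(a, tip)]
            out += [(a, x) for x in insert(b, tip)]
        return out

    forest = [0]
    for tip in range(1, n_tips):
        forest = [t for base in forest for t in insert(base, tip)]

    def to_tree(shape):
        parent, counter = {}, [n_tips]

        def walk(node):
            if isinstance(node, int):
                return node
            my_id = counter[0]
            counter[0] += 1
            a, b = walk(node[0]), walk(node[1])
            parent[a] = my_id
            parent[b] = my_id
            return my_id

        root = walk(shape)
        n_nodes = counter[0]
        arr = np.full(n_nodes, -1, dtype=np.int64)
        for child, par in parent.items():
            arr[child] = par
        return Tree(arr, [f"t{i}" for i in range(n_tips)])

    return [to_tree(s) for s in forest]


def brute_force_parsimony(column, tree: Tree) -> int:
    """Minimum changes over all internal-state assignments (missing free)."""
    column = list(column)
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    free_tips = [v for v in range(tree.n_tips) if column[v] == MISSING]
    best = np.inf
    for tip_states in itertools.product([0, 1], repeat=len(free_tips)):
        col = list(column)
        for v, s in zip(free_tips, tip_states):
            col[v] = s
        for states in itertools.product([0, 1], repeat=len(internal)):
            assign = dict(zip(internal, states))
            full = {v: col[v] for v in range(tree.n_tips)}
            full.update(assign)
            changes = sum(
                full[v] != full[p]
                for v, p in enumerate(tree.parent)
                if p >= 0
            )
            best = min(best, changes)
    return int(best)


def min_parsimony_over_trees(columns, n_tips: int, weights=None):
    """Exhaustive-search best total parsimony score over all topologies."""
    weights = [1] * len(columns) if weights is None else weights
    from clonetime.phylogeny import fitch_scores

    best = np.inf
    cols = np.asarray(columns)
    w = np.asarray(weights)
    for tree in enumerate_rooted_trees(n_tips):
        score = int(fitch_scores(tree, cols) @ w)
        best = min(best, score)
    return int(best)
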