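"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (explicit enumeration, definitional
formulas) and shares no code path with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import networkx as nx
import numpy as np

from ohnolog_forge.trees import TreeNode

# ---------------------------------------------------------------------------
# four-species reconciliation oracle
# ---------------------------------------------------------------------------

SP4_NEWICK = "((A,B)AB,(C,D)CD)R;"
SP4_CLADES = {
    "A": {"A"}, "B": {"B"}, "C": {"C"}, "D": {"D"},
    "AB": {"A", "B"}, "CD": {"C", "D"}, "R": {"A", "B", "C", "D"},
}


def oracle_lca(species: set[str]) -> str:
    """Smallest named clade of the fixed 4-species tree containing the set."""
    candidates = [name for name, clade in SP4_CLADES.items() if species <= clade]
    return min(candidates, key=lambda n: len(SP4_CLADES[n]))


def oracle_reconcile(root: TreeNode, species_of: dict[str, str]) -> dict[str, tuple]:
    """Event + mapped taxon per internal node, by direct definition.
    Returns {node_name: (event, taxon)} keyed by a postorder index name."""
    out = {}
    def recurse(node, counter=[0]):
        if node.is_leaf:
            return {species_of[node.name]}
        child_sets = [recurse(c) for c in node.children]
        species = set().union(*child_sets)
        taxon = oracle_lca(species)
        event = "duplication" if any(
            oracle_lca(cs) == taxon for cs in child_sets) else "speciation"
        counter[0] += 1
        out[id(node)] = (event, taxon)
        return species
    recurse(root)
    return out


@lru_cache(maxsize=None)
def tree_shapes(n: int) -> tuple:
    """All unordered rooted binary tree shapes with n leaves (nested tuples)."""
    if n == 1:
        return ("leaf",)
    shapes: set = set()
    for i in range(1, n // 2 + 1):
        for left in tree_shapes(i):
            for right in tree_shapes(n - i):
                shapes.add(tuple(sorted((left, right), key=repr)))
    return tuple(sorted(shapes, key=repr))


def build_shape(shape, labels: list[str]) -> TreeNode:
    """TreeNode tree from a shape, consuming species labels left to right;
    leaf names are unique gene ids g0, g1, ..."""
    counter = [0]
    def build(s):
        node = TreeNode()
        if s == "leaf":
            node.name = f"g{counter[0]}"
            counter[0] += 1
            return node
        for child in s:
            node.add_child(build(child))
        return node
    root = build(shape)
    species_of = {}
    for leaf, label in zip(root.leaves(), labels):
        species_of[leaf.name] = label
    return root, species_of


def count_leaves(shape) -> int:
    if shape == "leaf":
        return 1
    return sum(count_leaves(c) for c in shape)


# ---------------------------------------------------------------------------
# collinear chaining oracle
# ---------------------------------------------------------------------------

def max_chain_size(anchors, max_gap: int) -> int:
    """Largest valid collinear chain among <=~12 anchors of one chromosome
    pair, by exhaustive subset enumeration."""
    best = 0
    for r in range(1, len(anchors) + 1):
        if r <= best:
            continue
        for subset in itertools.combinations(anchors, r):
            for sign in (1, -1):
                chain = sorted(subset, key=lambda a: (a.pos_a, sign * a.pos_b))
                ok = True
                for prev, cur in zip(chain, chain[1:]):
                    dx = cur.pos_a - prev.pos_a
                    dy = (cur.pos_b - prev.pos_b) * sign
                    if dx <= 0 or dy <= 0 or dx - 1 > max_gap or dy - 1 > max_gap:
                        ok = False
                        break
                if ok:
                    best = max(best, r)
                    break
    return best


# ---------------------------------------------------------------------------
# betweenness oracle
# ---------------------------------------------------------------------------

def brute_betweenness(g: nx.Graph) -> dict[str, float]:
    """Relative betweenness by enumerating all shortest paths per node pair."""
    nodes = list(g.nodes)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    directed = g.is_directed()
    pairs = (itertools.permutations(nodes, 2) if directed
             else itertools.combinations(nodes, 2))
    for s, t in pairs:
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            on = sum(1 for p in paths if v in p)
            bc[v] += on / len(paths)
    norm = (n - 1) * (n - 2) if directed else (n - 1) * (n - 2) / 2
    return {v: bc[v] / norm for v in nodes} if norm else bc


# ---------------------------------------------------------------------------
# hypergeometric enumeration oracle
# ---------------------------------------------------------------------------

def enum_hypergeom(N: int, K: int, n: int, k: int, direction: str) -> float:
    """Tail probability by enumerating every size-n draw from N items."""
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        h = len(term & set(draw))
        total += 1
        if direction == "over" and h >= k:
            hits += 1
        elif direction == "under" and h <= k:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# correlation-from-definition oracles
# ---------------------------------------------------------------------------

def pearson_def(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def _ranks(x) -> np.ndarray:
    order = np.argsort(x)
    ranks = np.empty(len(x))
    ranks[order] = np.arange(1, len(x) + 1)
    return ranks


def spearman_def(x, y) -> float:
    return pearson_def(_ranks(x), _ranks(y))


def kendall_def(x, y) -> float:
    """Tau-a over tie-free vectors: (concordant - discordant) / C(n, 2)."""
    n = len(x)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += int(np.sign((x[i] - x[j]) * (y[i] - y[j])))
    return s / (n * (n - 1) / 2)
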