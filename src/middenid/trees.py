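"""Unrooted leaf-labeled trees: topology, splits, Newick, SPR, consensus.

Trees are stored as a plain adjacency map.  Leaves are string labels,
internal nodes are integers.  An unrooted binary tree has internal
degree 3 throughout; consensus trees may be multifurcating.  Topology
identity is the set of non-trivial splits (bipartitions), each split
canonicalized to the side not containing the lexicographically smallest
leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import dendropy


def _nkey(n) -> tuple:
    # deterministic ordering over mixed str/int node ids
    return (0, n) if isinstance(n, str) else (1, n)


@dataclass
class Tree:
    adj: dict[object, list]
    root: object | None = None               # set only for rooted trees
    supports: dict[frozenset, float] = field(default_factory=dict)

    # -- basics ---------------------------------------------------------
    def leaves(self) -> list[str]:
        return sorted(n for n in self.adj if isinstance(n, str))

    def internal(self) -> list[int]:
        return sorted(n for n in self.adj if not isinstance(n, str))

    def copy(self) -> "Tree":
        return Tree({k: list(v) for k, v in self.adj.items()}, self.root,
                    dict(self.supports))

    def edges(self) -> list[tuple]:
        """All edges, deterministically ordered."""
        out = []
        for u in sorted(self.adj, key=_nkey):
            for v in self.adj[u]:
                if _nkey(u) < _nkey(v):
                    out.append((u, v))
        return out

    def _new_internal(self) -> int:
        ints = [n for n in self.adj if isinstance(n, int)]
        return (max(ints) + 1) if ints else 0

    def _side_leaves(self, u, v) -> frozenset:
        """Leaves on v's side of edge (u, v)."""
        seen = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if isinstance(node, str):
                seen.add(node)
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        return frozenset(seen)

    # -- splits and identity -------------------------------------------
    def splits(self) -> frozenset:
        """Non-trivial splits, each as the side excluding the anchor leaf."""
        leaves = self.leaves()
        if len(leaves) < 4:
            return frozenset()
        anchor = leaves[0]
        all_leaves = frozenset(leaves)
        out = set()
        for u, v in self.edges():
            if isinstance(u, str) or isinstance(v, str):
                continue
            side = self._side_leaves(u, v)
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return frozenset(out)

    def topology_key(self) -> tuple:
        return (frozenset(self.leaves()), self.splits())

    # -- construction ---------------------------------------------------
    @staticmethod
    def star(leaves: list[str]) -> "Tree":
        """One internal node joined to every leaf."""
        if len(leaves) < 3:
            raise ValueError("star tree needs >= 3 leaves")
        adj: dict = {0: list(leaves)}
        for lf in leaves:
            adj[lf] = [0]
        return Tree(adj)

    def insert_leaf(self, leaf: str, edge: tuple) -> "Tree":
        """New tree with ``leaf`` attached to the midpoint of ``edge``."""
        if leaf in self.adj:
            raise ValueError(f"duplicate leaf label {leaf!r}")
        u, v = edge
        t = self.copy()
        w = t._new_internal()
        t.adj[u] = [w if x == v else x for x in t.adj[u]]
        t.adj[v] = [w if x == u else x for x in t.adj[v]]
        t.adj[w] = [u, v, leaf]
        t.adj[leaf] = [w]
        return t

    # -- Newick ---------------------------------------------------------
    def newick(self, with_support: bool = False) -> str:
        """Deterministic Newick string (terminating semicolon included)."""
        leaves = self.leaves()
        if len(leaves) < 2:
            raise ValueError("Newick output needs >= 2 leaves")
        if len(leaves) != len(set(leaves)):
            raise ValueError("duplicate leaf labels")

        all_leaves = frozenset(leaves)
        anchor = leaves[0]

        def min_leaf(node, parent) -> str:
            if isinstance(node, str):
                return node
            return min(min_leaf(nb, node) for nb in self.adj[node] if nb != parent)

        def write(node, parent) -> str:
            if isinstance(node, str):
                return node
            kids = sorted(
                (nb for nb in self.adj[node] if nb != parent),
                key=lambda nb: min_leaf(nb, node),
            )
            inner = ",".join(write(k, node) for k in kids)
            label = ""
            if with_support and parent is not None:
                side = self._side_leaves(parent, node)
                canon = side if anchor not in side else all_leaves - side
                if canon in self.supports:
                    label = f"{self.supports[canon]:g}"
            return f"({inner}){label}"

        if self.root is not None:
            return write(self.root, None) + ";"
        if len(leaves) == 2:
            return f"({leaves[0]},{leaves[1]});"
        start = self.adj[anchor][0]  # root the output at the anchor's neighbor
        return write(start, None) + ";"

    @staticmethod
    def from_newick(text: str) -> "Tree":
        """Parse a Newick string (topology only) into an unrooted Tree."""
        dt = dendropy.Tree.get(
            file=StringIO(text), schema="newick", preserve_underscores=True
        )
        adj: dict = {}
        next_id = [0]
        ids: dict = {}

        def node_id(nd):
            if nd not in ids:
                if nd.is_leaf():
                    ids[nd] = nd.taxon.label if nd.taxon else nd.label
                else:
                    ids[nd] = next_id[0]
                    next_id[0] += 1
            return ids[nd]

        for nd in dt.preorder_node_iter():
            adj.setdefault(node_id(nd), [])
            for ch in nd.child_nodes():
                adj[node_id(nd)].append(node_id(ch))
                adj.setdefault(node_id(ch), []).append(node_id(nd))
        t = Tree(adj)
        # suppress a degree-2 root (rooted Newick of an unrooted tree)
        for n in list(t.adj):
            if not isinstance(n, str) and len(t.adj[n]) == 2:
                a, b = t.adj[n]
                t.adj[a] = [b if x == n else x for x in t.adj[a]]
                t.adj[b] = [a if x == n else x for x in t.adj[b]]
                del t.adj[n]
        return t

    # -- rooting --------------------------------------------------------
    def root_with_outgroup(self, label: str) -> "Tree":
        """Root on the outgroup's pendant edge; splits are unchanged."""
        if label not in self.adj or not isinstance(label, str):
            raise ValueError(f"outgroup leaf {label!r} not in tree")
        t = self.copy()
        (u,) = t.adj[label]
        r = t._new_internal()
        t.adj[label] = [r]
        t.adj[u] = [r if x == label else x for x in t.adj[u]]
        t.adj[r] = [label, u]
        t.root = r
        return t

    def unroot(self) -> "Tree":
        if self.root is None:
            return self.copy()
        t = self.copy()
        r = t.root
        a, b = t.adj[r]
        t.adj[a] = [b if x == r else x for x in t.adj[a]]
        t.adj[b] = [a if x == r else x for x in t.adj[b]]
        del t.adj[r]
        t.root = None
        return t


# -- SPR neighborhood ----------------------------------------------------

def spr_neighbors(tree: Tree):
    """Yield SPR rearrangements of an unrooted binary tree, deterministically.

    Each directed edge (u, v) prunes the subtree on v's side; the
    remaining tree (with u suppressed if it drops to degree 2) offers
    every edge as a regraft point.
    """
    for u, v in _directed_edges(tree):
        pruned_nodes = _subtree_nodes(tree, u, v)
        remaining = {n for n in tree.adj if n not in pruned_nodes}
        rem_leaves = [n for n in remaining if isinstance(n, str)]
        if len(rem_leaves) < 2:
            continue
        base = tree.copy()
        # cut the edge
        base.adj[u] = [x for x in base.adj[u] if x != v]
        base.adj[v] = [x for x in base.adj[v] if x != u]
        # suppress u if it became degree 2 (internal nodes only)
        if not isinstance(u, str) and len(base.adj[u]) == 2:
            a, b = base.adj[u]
            base.adj[a] = [b if x == u else x for x in base.adj[a]]
            base.adj[b] = [a if x == u else x for x in base.adj[b]]
            del base.adj[u]
        elif not isinstance(u, str) and len(base.adj[u]) < 2:
            continue  # degenerate (u was the only junction)
        rem_edges = [
            (x, y)
            for x in sorted(base.adj, key=_nkey)
            for y in base.adj[x]
            if _nkey(x) < _nkey(y) and x not in pruned_nodes and y not in pruned_nodes
        ]
        for x, y in rem_edges:
            t = Tree({k: list(vv) for k, vv in base.adj.items()})
            w = t._new_internal()
            t.adj[x] = [w if z == y else z for z in t.adj[x]]
            t.adj[y] = [w if z == x else z for z in t.adj[y]]
            t.adj[w] = [x, y, v]
            t.adj[v] = t.adj[v] + [w]
            yield t


def _directed_edges(tree: Tree):
    for u, v in tree.edges():
        yield (u, v)
        yield (v, u)


def _subtree_nodes(tree: Tree, u, v) -> set:
    """All nodes on v's side of edge (u, v), including v."""
    seen = {v}
    stack = [(v, u)]
    while stack:
        node, parent = stack.pop()
        for nb in tree.adj[node]:
            if nb != parent and nb not in seen:
                seen.add(nb)
                stack.append((nb, node))
    return seen


# -- consensus -----------------------------------------------------------

def majority_consensus(trees: list[Tree], threshold: float = 0.5) -> Tree:
    """Majority-rule consensus: splits in > ``threshold`` of the input trees.

    The result may be multifurcating; per-split support fractions are
    attached as ``supports``.
    """
    if not trees:
        raise ValueError("majority_consensus requires at least one tree")
    leafsets = {frozenset(t.leaves()) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("trees have different leaf sets")
    leaves = trees[0].leaves()
    n = len(trees)

    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    kept = {s: c / n for s, c in counts.items() if c / n > threshold}

    # build the (rooted-at-anchor) cluster hierarchy; clusters are laminar
    anchor = leaves[0]
    clusters = sorted(kept, key=lambda s: (-len(s), sorted(s)))
    adj: dict = {0: []}
    node_of: dict[frozenset, int] = {}
    parent_of: dict[frozenset, int] = {}
    nid = 1
    for c in clusters:
        parent = 0
        best = None
        for other in clusters:
            if other is not c and c < other:
                if best is None or len(other) < len(best):
                    best = other
        if best is not None:
            parent = node_of[best]
        node_of[c] = nid
        parent_of[c] = parent
        adj[nid] = [parent]
        adj[parent].append(nid)
        nid += 1
    for lf in leaves:
        if lf == anchor:
            parent = 0
        else:
            best = None
            for c in clusters:
                if lf in c and (best is None or len(c) < len(best)):
                    best = c
            parent = node_of[best] if best is not None else 0
        adj[lf] = [parent]
        adj[parent].append(lf)

    out = Tree(adj)
    out.supports = dict(kept)
    return out


# -- enumeration ---------------------------------------------------------

def all_topologies(leaves: list[str]):
    """Yield every unrooted binary topology over the leaf set.

    (2n-5)!! trees; callers must keep n small.
    """
    leaves = sorted(leaves)
    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves")

    def grow(tree: Tree, remaining: list[str]):
        if not remaining:
            yield tree
            return
        leaf, rest = remaining[0], remaining[1:]
        for edge in tree.edges():
            yield from grow(tree.insert_leaf(leaf, edge), rest)

    yield from grow(Tree.star(leaves[:3]), leaves[3:])
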