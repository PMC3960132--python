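"""Maximum parsimony with alignment gaps as a fifth character state.

Very short ribosomal alignments can carry most of their phylogenetic
signal in indels.  Treating '-' as an ordinary fifth state (rather than
missing data) keeps that signal: each character is a subset of
{A,C,G,T,GAP}, Fitch's algorithm counts the minimum number of state
changes per column, and tree search proceeds by random-addition
stepwise insertion followed by branch swapping, pooling all equally
parsimonious topologies and summarizing them with a majority-rule
consensus.

``N`` encodes an unread base — something was there, it just could not
be called — so it maps to {A,C,G,T}, never to the gap state.  Only a
literal '-' is the definite fifth state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seq import IUPAC_SETS
from .trees import Tree, all_topologies, majority_consensus, spr_neighbors, _nkey

#: bitmask encoding of the five states
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "-": 16}
_FULL_BASES = 15  # {A,C,G,T}

_SYMBOL_MASK: dict[str, int] = {"-": 16}
for code, bases in IUPAC_SETS.items():
    _SYMBOL_MASK[code] = sum(_BIT[b] for b in bases)


@dataclass
class CharacterMatrix:
    """Taxa-by-sites matrix of 5-state sets, encoded as uint8 bitmasks."""

    taxa: list[str]
    states: np.ndarray              # shape (n_taxa, n_sites), uint8, nonzero
    weights: np.ndarray | None = None  # per-site multiplicities

    def __post_init__(self) -> None:
        if len(self.taxa) != self.states.shape[0]:
            raise ValueError("taxa/states shape mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if (self.states == 0).any():
            raise ValueError("empty state set in matrix")
        if self.weights is None:
            self.weights = np.ones(self.states.shape[1], dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return int(self.states.shape[1])

    def compressed(self) -> "CharacterMatrix":
        """Collapse duplicate columns into weights (scores unchanged)."""
        cols, inv = np.unique(self.states, axis=1, return_inverse=True)
        w = np.zeros(cols.shape[1], dtype=np.int64)
        np.add.at(w, inv, self.weights)
        return CharacterMatrix(self.taxa, cols, w)


@dataclass
class ParsimonyResult:
    best_score: int
    optimal_trees: list[Tree]
    consensus: Tree
    settings: dict = field(default_factory=dict)


def encode_states(alignment: list[tuple[str, str]]) -> CharacterMatrix:
    """Encode an equal-length gapped alignment into a CharacterMatrix."""
    if not alignment:
        raise ValueError("empty alignment")
    lengths = {len(seq) for _, seq in alignment}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    taxa = [label for label, _ in alignment]
    rows = []
    for label, seq in alignment:
        try:
            rows.append([_SYMBOL_MASK[c] for c in seq])
        except KeyError as exc:
            raise ValueError(
                f"illegal symbol {exc.args[0]!r} in row {label!r}"
            ) from None
    return CharacterMatrix(taxa, np.array(rows, dtype=np.uint8))


def fitch_length(tree: Tree, m: CharacterMatrix) -> int:
    """Fitch small-parsimony length of the tree (sum over columns).

    The tree must be unrooted binary over exactly the matrix taxa; the
    count is invariant to where the computation is rooted.
    """
    t = tree.unroot() if tree.root is not None else tree
    if set(t.leaves()) != set(m.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    rows = {taxon: m.states[i] for i, taxon in enumerate(m.taxa)}
    return _fitch_steps(t, rows, m.weights)


def _fitch_steps(t: Tree, rows: dict[str, np.ndarray], weights: np.ndarray) -> int:
    leaves = t.leaves()
    if len(leaves) == 2:
        a, b = leaves
        return int((( (rows[a] & rows[b]) == 0) * weights).sum())
    anchor = leaves[0]
    start = t.adj[anchor][0]
    order: list[tuple] = []
    stack = [(start, anchor)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        if not isinstance(node, str):
            for nb in t.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
    steps = np.zeros(weights.shape[0], dtype=np.int64)
    sets: dict = {}
    for node, parent in reversed(order):
        if isinstance(node, str):
            sets[node] = rows[node]
            continue
        kids = [nb for nb in t.adj[node] if nb != parent]
        s = sets[kids[0]]
        for k in kids[1:]:
            inter = s & sets[k]
            miss = inter == 0
            steps += miss
            s = np.where(miss, s | sets[k], inter)
        sets[node] = s
    # close the rooting edge (anchor leaf vs the rest of the tree)
    steps += (sets[start] & rows[anchor]) == 0
    return int((steps * weights).sum())


def exhaustive_search(m: CharacterMatrix, max_taxa: int = 9) -> ParsimonyResult:
    """Enumerate every unrooted binary topology (exact oracle, small n)."""
    if len(m.taxa) > max_taxa:
        raise ValueError(
            f"exhaustive search limited to {max_taxa} taxa, got {len(m.taxa)}"
        )
    if len(m.taxa) < 4:
        raise ValueError("exhaustive search needs >= 4 taxa")
    mc = m.compressed()
    rows = {taxon: mc.states[i] for i, taxon in enumerate(mc.taxa)}
    best = math.inf
    optimal: list[Tree] = []
    for t in all_topologies(m.taxa):
        s = _fitch_steps(t, rows, mc.weights)
        if s < best:
            best, optimal = s, [t]
        elif s == best:
            optimal.append(t)
    cons = majority_consensus(optimal)
    return ParsimonyResult(int(best), optimal, cons, {"method": "exhaustive"})


def random_addition_tree(m: CharacterMatrix, order: list[str]) -> Tree:
    """Stepwise addition: insert each taxon on the edge minimizing length.

    Ties are broken by the first edge in the tree's deterministic edge
    ordering, so the addition order fully determines the result.
    """
    if sorted(order) != sorted(m.taxa):
        raise ValueError("addition order must be a permutation of the taxa")
    if len(order) < 3:
        raise ValueError("need >= 3 taxa")
    mc = m.compressed()
    rows = {taxon: mc.states[i] for i, taxon in enumerate(mc.taxa)}
    tree = Tree.star(list(order[:3]))
    for taxon in order[3:]:
        sub_rows = {k: rows[k] for k in tree.leaves()}
        sub_rows[taxon] = rows[taxon]
        best_tree, best_score = None, math.inf
        for edge in tree.edges():
            cand = tree.insert_leaf(taxon, edge)
            s = _fitch_steps(cand, sub_rows, mc.weights)
            if s < best_score:
                best_tree, best_score = cand, s
        tree = best_tree
    return tree


def _local_search(tree: Tree, rows, weights, swap: str) -> tuple[Tree, int]:
    """First-improvement branch swapping to a local optimum."""
    score = _fitch_steps(tree, rows, weights)
    if swap == "NONE":
        return tree, score
    improved = True
    while improved:
        improved = False
        for cand in _neighbors(tree, swap):
            s = _fitch_steps(cand, rows, weights)
            if s < score:
                tree, score = cand, s
                improved = True
                break
    return tree, score


def _neighbors(tree: Tree, swap: str):
    if swap == "SPR":
        yield from spr_neighbors(tree)
    elif swap == "NNI":
        yield from _nni_neighbors(tree)
    else:
        raise ValueError(f"unknown swap strategy {swap!r}")


def _nni_neighbors(tree: Tree):
    """The two nearest-neighbor interchanges around each internal edge."""
    for u, v in tree.edges():
        if isinstance(u, str) or isinstance(v, str):
            continue
        u_nbs = sorted((x for x in tree.adj[u] if x != v), key=_nkey)
        v_nbs = sorted((x for x in tree.adj[v] if x != u), key=_nkey)
        a = u_nbs[0]
        for b in v_nbs:
            t = tree.copy()
            t.adj[u] = [b if x == a else x for x in t.adj[u]]
            t.adj[v] = [a if x == b else x for x in t.adj[v]]
            t.adj[a] = [v if x == u else x for x in t.adj[a]]
            t.adj[b] = [u if x == v else x for x in t.adj[b]]
            yield t


def heuristic_search(
    m: CharacterMatrix,
    n_starts: int = 1000,
    swap: str = "SPR",
    seed: int = 0,
) -> ParsimonyResult:
    """Random-addition heuristic search with branch swapping.

    ``n_starts`` independent random addition orders are drawn from a
    seeded generator; each start is refined to a local optimum, local
    optima are pooled, and the distinct topologies attaining the best
    score (identified by canonical split sets) form the co-optimal set.
    """
    if len(m.taxa) < 4:
        raise ValueError("heuristic search needs >= 4 taxa")
    mc = m.compressed()
    rows = {taxon: mc.states[i] for i, taxon in enumerate(mc.taxa)}
    rng = np.random.default_rng(seed)
    taxa = list(m.taxa)

    pool: dict[tuple, tuple[Tree, int]] = {}
    log: list[int] = []
    for _ in range(n_starts):
        order = [taxa[i] for i in rng.permutation(len(taxa))]
        t = random_addition_tree(m, order)
        t, s = _local_search(t, rows, mc.weights, swap)
        log.append(s)
        key = t.topology_key()
        if key not in pool or s < pool[key][1]:
            pool[key] = (t, s)

    best = min(s for _, s in pool.values())
    optimal = [t for t, s in pool.values() if s == best]
    optimal.sort(key=lambda t: sorted(map(sorted, t.splits())))
    cons = majority_consensus(optimal)
    return ParsimonyResult(
        int(best),
        optimal,
        cons,
        {
            "method": "heuristic",
            "n_starts": n_starts,
            "swap": swap,
            "seed": seed,
            "start_scores": log,
        },
    )
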