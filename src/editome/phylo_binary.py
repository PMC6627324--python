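"""Tree inference from binary editing-site characters.

Implements the distance and parsimony route of the editing-site phylogeny:
p-distances on presence/absence rows, neighbor-joining with deterministic
tie-breaking, Fitch small parsimony (vectorized over characters), parsimony
search (exhaustive for small taxon sets, NNI hill-climbing otherwise),
character bootstrap, and strict >cutoff majority-rule consensus.

Trees are unrooted; internally they are stored as an adjacency map over
integer node ids with leaves carrying taxon names. Splits are canonicalized
as the side not containing the alphabetically first taxon.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

from .edit_matrix import BinaryEditingMatrix

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "ParsimonyResult",
    "hamming_distances",
    "neighbor_joining",
    "fitch_score",
    "enumerate_topologies",
    "parsimony_search",
    "nni_neighbors",
    "bootstrap_trees",
    "majority_consensus",
    "to_newick",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class PhyloTree:
    """Unrooted tree: adjacency over node ids, leaf id -> taxon name."""

    adjacency: dict[int, list[int]]
    leaves: dict[int, str]
    branch_lengths: dict[frozenset[int], float] = field(default_factory=dict)
    supports: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.leaves.values())

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            adjacency={k: list(v) for k, v in self.adjacency.items()},
            leaves=dict(self.leaves),
            branch_lengths=dict(self.branch_lengths),
            supports=dict(self.supports),
        )

    def splits(self) -> set[frozenset[str]]:
        """Internal bipartitions, each as the side without the first taxon."""
        all_taxa = frozenset(self.leaves.values())
        anchor = min(all_taxa)
        n = len(all_taxa)
        out: set[frozenset[str]] = set()
        root = self._internal_root()
        for _, child, cluster in _edge_clusters(self, root):
            if 2 <= len(cluster) <= n - 2:
                side = frozenset(cluster)
                if anchor in side:
                    side = all_taxa - side
                out.add(side)
        return out

    def _internal_root(self) -> int:
        for node, nbrs in self.adjacency.items():
            if len(nbrs) > 1:
                return node
        return next(iter(self.adjacency))


def _postorder(tree: PhyloTree, root: int) -> list[tuple[int, int]]:
    """(parent, node) pairs in postorder starting below ``root``."""
    order: list[tuple[int, int]] = []
    stack = [(root, -1)]
    seen = []
    while stack:
        node, parent = stack.pop()
        seen.append((parent, node))
        for nbr in tree.adjacency[node]:
            if nbr != parent:
                stack.append((nbr, node))
    seen.reverse()
    return seen


def _edge_clusters(tree: PhyloTree, root: int) -> list[tuple[int, int, set[str]]]:
    """Leaf clusters below each directed edge away from ``root``."""
    clusters: dict[int, set[str]] = {}
    out = []
    for parent, node in _postorder(tree, root):
        if node in tree.leaves:
            clusters[node] = {tree.leaves[node]}
        else:
            clusters[node] = set()
            for nbr in tree.adjacency[node]:
                if nbr != parent:
                    clusters[node] |= clusters[nbr]
        if parent != -1:
            out.append((parent, node, clusters[node]))
    return out


def hamming_distances(matrix: BinaryEditingMatrix) -> DistanceMatrix:
    """p-distance: fraction of characters differing between two rows."""
    if matrix.width == 0:
        raise ValueError("matrix has no characters")
    if len(matrix.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    cells = matrix.cells.astype(np.int16)
    diff = np.abs(cells[:, None, :] - cells[None, :, :]).sum(axis=2)
    return DistanceMatrix(taxa=list(matrix.taxa), values=diff / matrix.width)


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining with the Q criterion.

    Ties on Q are broken by the lexicographically smallest pair of cluster
    labels (a cluster's label is the alphabetically first taxon it holds),
    so the output is stable across runs. Negative branch lengths are
    clamped to zero with the deficit logged.
    """
    n = len(dist.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    leaves = dict(enumerate(dist.taxa))
    adjacency: dict[int, list[int]] = {i: [] for i in range(n)}
    lengths: dict[frozenset[int], float] = {}
    next_id = n

    active: list[int] = list(range(n))
    d: dict[frozenset[int], float] = {}
    for i, j in itertools.combinations(range(n), 2):
        d[frozenset((i, j))] = float(dist.values[i, j])
    label = {i: dist.taxa[i] for i in range(n)}

    def dget(a: int, b: int) -> float:
        return d[frozenset((a, b))]

    def add_edge(a: int, b: int, length: float) -> None:
        if length < 0:
            logger.debug("clamping negative branch length %.4g to 0", length)
            length = 0.0
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
        lengths[frozenset((a, b))] = length

    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(dget(a, b) for b in active if b != a) for a in active}
        best: Optional[tuple[float, tuple[str, str], int, int]] = None
        for a, b in itertools.combinations(active, 2):
            q = (r - 2) * dget(a, b) - row_sum[a] - row_sum[b]
            key = (q, tuple(sorted((label[a], label[b]))))
            if best is None or key < (best[0], best[1]):
                best = (q, key[1], a, b)
        _, _, i, j = best
        new = next_id
        next_id += 1
        li = 0.5 * dget(i, j) + (row_sum[i] - row_sum[j]) / (2 * (r - 2))
        lj = dget(i, j) - li
        add_edge(new, i, li)
        add_edge(new, j, lj)
        for a in active:
            if a in (i, j):
                continue
            d[frozenset((new, a))] = 0.5 * (dget(i, a) + dget(j, a) - dget(i, j))
        label[new] = min(label[i], label[j])
        active = [a for a in active if a not in (i, j)] + [new]

    i, j, k = active
    center = next_id
    add_edge(center, i, 0.5 * (dget(i, j) + dget(i, k) - dget(j, k)))
    add_edge(center, j, 0.5 * (dget(i, j) + dget(j, k) - dget(i, k)))
    add_edge(center, k, 0.5 * (dget(i, k) + dget(j, k) - dget(i, j)))
    return PhyloTree(adjacency=adjacency, leaves=leaves, branch_lengths=lengths)


def _leaf_codes(tree: PhyloTree, matrix: BinaryEditingMatrix) -> dict[int, np.ndarray]:
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    codes = {}
    for node, name in tree.leaves.items():
        codes[node] = matrix.cells[row_of[name]].astype(np.uint8) + 1  # {0}->1, {1}->2
    return codes


def fitch_score(tree: PhyloTree, matrix: BinaryEditingMatrix) -> int:
    """Fitch small-parsimony change count summed over all characters.

    Characters are unordered binary with equal weight; the count is
    independent of the rooting used for the traversal.
    """
    if set(tree.leaves.values()) != set(matrix.taxa):
        raise ValueError("tree leaf set does not match matrix taxa")
    codes = _leaf_codes(tree, matrix)
    changes = np.zeros(matrix.width, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    root = tree._internal_root()
    for parent, node in _postorder(tree, root):
        if node in tree.leaves:
            sets[node] = codes[node]
            continue
        acc: Optional[np.ndarray] = None
        for nbr in tree.adjacency[node]:
            if nbr == parent:
                continue
            child = sets[nbr]
            if acc is None:
                acc = child.copy()
            else:
                inter = acc & child
                empty = inter == 0
                changes[empty] += 1
                acc = np.where(empty, acc | child, inter).astype(np.uint8)
        sets[node] = acc
    return int(changes.sum())


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[PhyloTree]:
    """All unrooted binary topologies over ``taxa`` by stepwise addition."""
    taxa = list(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    base = PhyloTree(
        adjacency={0: [n], 1: [n], 2: [n], n: [0, 1, 2]},
        leaves={i: taxa[i] for i in range(3)},
    )
    base.leaves = {i: taxa[i] for i in range(n)}  # names for leaves added later

    def expand(tree: PhyloTree, leaf: int, next_internal: int) -> Iterator[PhyloTree]:
        if leaf == n:
            yield tree
            return
        edges = {
            frozenset((u, v))
            for u, nbrs in tree.adjacency.items()
            for v in nbrs
        }
        for edge in sorted(edges, key=sorted):
            u, v = sorted(edge)
            t = tree.copy()
            t.adjacency[u].remove(v)
            t.adjacency[v].remove(u)
            mid = next_internal
            t.adjacency[mid] = [u, v, leaf]
            t.adjacency[u].append(mid)
            t.adjacency[v].append(mid)
            t.adjacency[leaf] = [mid]
            yield from expand(t, leaf + 1, next_internal + 1)

    yield from expand(base, 3, n + 1)


def nni_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """The two nearest-neighbor interchanges around every internal edge."""
    internal = [u for u, nbrs in tree.adjacency.items() if len(nbrs) > 1]
    for u, v in itertools.combinations(internal, 2):
        if v not in tree.adjacency[u]:
            continue
        a_side = [x for x in tree.adjacency[u] if x != v]
        b_side = [x for x in tree.adjacency[v] if x != u]
        if len(a_side) != 2 or len(b_side) != 2:
            continue  # NNI defined on binary internal edges
        b = a_side[1]
        for c in b_side:
            t = tree.copy()
            t.adjacency[u].remove(b)
            t.adjacency[v].remove(c)
            t.adjacency[u].append(c)
            t.adjacency[v].append(b)
            t.adjacency[b].remove(u)
            t.adjacency[b].append(v)
            t.adjacency[c].remove(v)
            t.adjacency[c].append(u)
            t.branch_lengths = {}
            yield t


def _random_topology(taxa: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    order = list(rng.permutation(len(taxa)))
    taxa = list(taxa)
    n = len(taxa)
    first = order[:3]
    center = n
    tree = PhyloTree(
        adjacency={first[0]: [center], first[1]: [center], first[2]: [center],
                   center: list(first)},
        leaves={i: taxa[i] for i in range(n)},
    )
    next_internal = n + 1
    for leaf in order[3:]:
        edges = sorted(
            {frozenset((u, v)) for u, nbrs in tree.adjacency.items() for v in nbrs},
            key=sorted,
        )
        u, v = sorted(edges[rng.integers(len(edges))])
        tree.adjacency[u].remove(v)
        tree.adjacency[v].remove(u)
        mid = next_internal
        next_internal += 1
        tree.adjacency[mid] = [u, v, leaf]
        tree.adjacency[u].append(mid)
        tree.adjacency[v].append(mid)
        tree.adjacency[leaf] = [mid]
    return tree


@dataclass
class ParsimonyResult:
    trees: list[PhyloTree]
    score: int


def parsimony_search(
    matrix: BinaryEditingMatrix,
    strategy: Literal["exhaustive", "nni"] = "nni",
    seed: Optional[int] = None,
    restarts: int = 3,
) -> ParsimonyResult:
    """Search for minimum-Fitch-score trees.

    ``exhaustive`` enumerates every unrooted binary topology (allowed up to
    9 taxa) and returns all optima. ``nni`` hill-climbs from the
    neighbor-joining tree, plus ``restarts - 1`` seeded random starting
    topologies, accepting the best improving interchange until none remains.
    """
    taxa = sorted(matrix.taxa)
    if len(taxa) < 4:
        raise ValueError("parsimony search needs at least 4 taxa")
    if strategy == "exhaustive":
        if len(taxa) > 9:
            raise ValueError("exhaustive search limited to 9 taxa; use strategy='nni'")
        best_score: Optional[int] = None
        best: list[PhyloTree] = []
        best_splits: list[set] = []
        for tree in enumerate_topologies(taxa):
            s = fitch_score(tree, matrix)
            if best_score is None or s < best_score:
                best_score, best, best_splits = s, [tree], [tree.splits()]
            elif s == best_score:
                sp = tree.splits()
                if sp not in best_splits:
                    best.append(tree)
                    best_splits.append(sp)
        return ParsimonyResult(trees=best, score=best_score)

    if strategy != "nni":
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    starts = [neighbor_joining(hamming_distances(matrix))]
    for _ in range(max(0, restarts - 1)):
        starts.append(_random_topology(taxa, rng))
    best_tree: Optional[PhyloTree] = None
    best_score = None
    for tree in starts:
        score = fitch_score(tree, matrix)
        improved = True
        while improved:
            improved = False
            for cand in nni_neighbors(tree):
                s = fitch_score(cand, matrix)
                if s < score:
                    tree, score = cand, s
                    improved = True
                    break
        if best_score is None or score < best_score:
            best_tree, best_score = tree, score
    return ParsimonyResult(trees=[best_tree], score=best_score)


def bootstrap_trees(
    matrix: BinaryEditingMatrix,
    method: Literal["mp", "nj"] = "mp",
    replicates: int = 1000,
    seed: Optional[int] = None,
) -> list[PhyloTree]:
    """Character bootstrap: resample columns with replacement, re-infer.

    Each replicate draws ``width`` characters with replacement and infers a
    tree by neighbor-joining (``nj``) or NNI parsimony search (``mp``).
    Fully deterministic under a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if matrix.width < 1:
        raise ValueError("matrix has no characters")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(replicates):
        cols = rng.integers(0, matrix.width, size=matrix.width)
        sub = BinaryEditingMatrix(
            taxa=list(matrix.taxa),
            characters=[matrix.characters[c] for c in cols],
            cells=matrix.cells[:, cols],
            direction=matrix.direction,
        )
        if method == "nj":
            out.append(neighbor_joining(hamming_distances(sub)))
        elif method == "mp":
            child_seed = int(rng.integers(2**31))
            out.append(parsimony_search(sub, "nni", seed=child_seed, restarts=1).trees[0])
        else:
            raise ValueError(f"unknown bootstrap method {method!r}")
    return out


def majority_consensus(trees: Sequence[PhyloTree], cutoff: float = 0.5) -> PhyloTree:
    """Strict majority-rule consensus with per-split support percentages.

    Splits occurring in more than ``cutoff`` of the trees are retained
    (support = 100 x frequency); no greedy completion with minority splits
    is attempted, so conflicting resolutions collapse to polytomies.
    """
    if not trees:
        raise ValueError("need at least one tree")
    taxa = set(trees[0].leaves.values())
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        if set(t.leaves.values()) != taxa:
            raise ValueError("trees have differing leaf sets")
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    keep = {s: c / len(trees) for s, c in counts.items() if c / len(trees) > cutoff}

    names = sorted(taxa)
    leaf_id = {name: i for i, name in enumerate(names)}
    adjacency: dict[int, list[int]] = {i: [] for i in range(len(names))}
    next_id = len(names)
    # items currently at the top level: (node id, taxon set)
    items: list[tuple[int, frozenset[str]]] = [
        (leaf_id[name], frozenset([name])) for name in names
    ]
    supports: dict[frozenset[str], float] = {}
    # build bottom-up: smaller clusters first, so nested clusters absorb
    # already-created nodes
    for split in sorted(keep, key=lambda s: (len(s), sorted(s))):
        inside = [(nid, ts) for nid, ts in items if ts <= split]
        covered = frozenset().union(*(ts for _, ts in inside)) if inside else frozenset()
        if covered != split:
            continue  # incompatible with an already-placed larger split
        node = next_id
        next_id += 1
        adjacency[node] = []
        for nid, _ in inside:
            adjacency[node].append(nid)
            adjacency[nid].append(node)
        items = [(nid, ts) for nid, ts in items if not ts <= split] + [(node, split)]
        supports[split] = 100.0 * keep[split]
    root = next_id
    adjacency[root] = []
    for nid, _ in items:
        adjacency[root].append(nid)
        adjacency[nid].append(root)
    return PhyloTree(
        adjacency=adjacency,
        leaves={leaf_id[n]: n for n in names},
        supports=supports,
    )


def to_newick(
    tree: PhyloTree,
    outgroup: Optional[str] = None,
    with_lengths: bool = False,
    with_supports: bool = False,
) -> str:
    """Serialize to Newick; display rooting on ``outgroup`` when given.

    Support values, when requested, are written as internal node labels.
    """
    all_taxa = frozenset(tree.leaves.values())
    anchor = min(all_taxa)
    name_to_id = {v: k for k, v in tree.leaves.items()}
    if outgroup is not None:
        if outgroup not in name_to_id:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf")
        root = tree.adjacency[name_to_id[outgroup]][0]
    else:
        root = tree._internal_root()

    def label_for(cluster: frozenset[str]) -> str:
        if not with_supports:
            return ""
        side = cluster if anchor not in cluster else all_taxa - cluster
        if side in tree.supports:
            return f"{tree.supports[side]:g}"
        return ""

    def render_with_cluster(node: int, parent: int) -> tuple[str, frozenset[str]]:
        if node in tree.leaves:
            body = tree.leaves[node]
            if with_lengths:
                length = tree.branch_lengths.get(frozenset((node, parent)), 0.0)
                body += f":{length:g}"
            return body, frozenset([tree.leaves[node]])
        parts, cluster_set = [], set()
        for nbr in tree.adjacency[node]:
            if nbr == parent:
                continue
            sub, sub_cluster = render_with_cluster(nbr, node)
            parts.append(sub)
            cluster_set |= set(sub_cluster)
        cluster = frozenset(cluster_set)
        body = "(" + ",".join(parts) + ")" + label_for(cluster)
        if with_lengths:
            length = tree.branch_lengths.get(frozenset((node, parent)), 0.0)
            body += f":{length:g}"
        return body, cluster

    parts = []
    for nbr in tree.adjacency[root]:
        parts.append(render_with_cluster(nbr, root)[0])
    return "(" + ",".join(parts) + ");"
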