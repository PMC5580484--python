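"""Distance-based phylogeny: p-distances, neighbor joining, minimum
evolution by close-neighbor-interchange, and column-resampling bootstrap.

The distance model is the uncorrected p-distance with pairwise deletion
(gaps and ambiguity codes ignored per pair): at the sub-percent divergence
this pipeline targets, multiple-hit correction is negligible and the
uncorrected proportion is checkable by hand.  Tree search minimizes the
minimum-evolution criterion — the sum of OLS branch-length estimates for a
fixed topology (negative estimates included in the sum) — by hill-climbing
over all nearest-neighbor-interchange rearrangements from a neighbor-
joining start tree.  Bootstrap support resamples alignment columns with
replacement and repeats distances -> NJ -> CNI per replicate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .align import MultiAlignment

_UNAMBIG = frozenset(b"ACGT")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix size does not match taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])


class Tree:
    """Unrooted tree: integer nodes, leaf labels, branch lengths.

    Leaves are nodes 0..n-1 in the order of ``labels``; internal nodes
    follow.  Branch lengths may be negative (OLS estimates); they are
    clamped to zero only at Newick output, with a flag.
    """

    def __init__(self, labels: list[str]):
        self.labels = list(labels)
        self.adj: dict[int, dict[int, float]] = {i: {} for i in range(len(labels))}
        self._next = len(labels)

    # -- construction -------------------------------------------------
    def new_node(self) -> int:
        node = self._next
        self.adj[node] = {}
        self._next += 1
        return node

    def link(self, a: int, b: int, length: float = 0.0) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    def unlink(self, a: int, b: int) -> None:
        del self.adj[a][b]
        del self.adj[b][a]

    def copy(self) -> "Tree":
        other = Tree(self.labels)
        other.adj = {u: dict(nbrs) for u, nbrs in self.adj.items()}
        other._next = self._next
        return other

    # -- queries ------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def is_leaf(self, node: int) -> bool:
        return node < len(self.labels)

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            {(min(u, v), max(u, v)) for u in self.adj for v in self.adj[u]}
        )

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v) for u, v in self.edges()
            if not self.is_leaf(u) and not self.is_leaf(v)
        ]

    def _leafset_beyond(self, start: int, forbidden: int) -> frozenset[int]:
        seen = set()
        stack = [start]
        leaves = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if self.is_leaf(node):
                leaves.add(node)
            for nbr in self.adj[node]:
                if nbr != forbidden and nbr not in seen:
                    stack.append(nbr)
        return frozenset(leaves)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the side NOT
        containing the lexicographically smallest taxon."""
        anchor = min(range(self.n_leaves), key=lambda i: self.labels[i])
        out = set()
        for u, v in self.internal_edges():
            side = self._leafset_beyond(u, v)
            if anchor in side:
                side = frozenset(range(self.n_leaves)) - side
            if 1 < len(side) < self.n_leaves - 1 or (
                1 < len(side) and self.n_leaves - len(side) > 1
            ):
                out.add(frozenset(self.labels[i] for i in side))
        return out

    def canonical_key(self):
        return tuple(sorted(tuple(sorted(s)) for s in self.splits()))

    def leaf_path_lengths(self) -> "DistanceMatrix":
        """Pairwise path lengths between leaves (the additive distances)."""
        n = self.n_leaves
        values = np.zeros((n, n))
        for leaf in range(n):
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                node = stack.pop()
                for nbr, length in self.adj[node].items():
                    if nbr not in dist:
                        dist[nbr] = dist[node] + length
                        stack.append(nbr)
            for other in range(n):
                values[leaf, other] = dist[other]
        return DistanceMatrix(self.labels, (values + values.T) / 2)

    # -- output -------------------------------------------------------
    def newick(
        self,
        root: int | None = None,
        supports: dict[frozenset[str], float] | None = None,
        clamp_negative: bool = True,
        outgroup: str | None = None,
    ) -> str:
        """Newick string; optionally rooted on the outgroup's pendant edge,
        with split supports as internal node labels."""
        if outgroup is not None:
            og = self.labels.index(outgroup)
            parent = next(iter(self.adj[og]))
            half = self.adj[og][parent] / 2

            def fmt(length: float) -> str:
                if clamp_negative and length < 0:
                    length = 0.0
                return format(length, ".6g")

            left = self._subtree_newick(og, parent, supports, clamp_negative)
            right = self._subtree_newick(parent, og, supports, clamp_negative)
            # re-split the pendant edge across the root
            left = left.rsplit(":", 1)[0] + f":{fmt(half)}"
            right = right.rsplit(":", 1)[0] + f":{fmt(half)}"
            return f"({left},{right});"
        if root is None:
            root = self.n_leaves  # first internal node
            if root not in self.adj:
                root = 0
        parts = [
            self._subtree_newick(child, root, supports, clamp_negative)
            for child in sorted(self.adj[root])
        ]
        label = self.labels[root] if self.is_leaf(root) else ""
        return f"({','.join(parts)}){label};"

    def _subtree_newick(self, node, parent, supports, clamp_negative) -> str:
        length = self.adj[node][parent]
        if clamp_negative and length < 0:
            length = 0.0
        blen = format(length, ".6g")
        if self.is_leaf(node):
            return f"{self.labels[node]}:{blen}"
        parts = [
            self._subtree_newick(child, node, supports, clamp_negative)
            for child in sorted(self.adj[node])
            if child != parent
        ]
        label = ""
        if supports is not None:
            side = self._leafset_beyond(node, parent)
            names = frozenset(self.labels[i] for i in side)
            anchor_names = frozenset(self.labels)
            for split, value in supports.items():
                if names == split or names == anchor_names - split:
                    label = format(value, ".4g")
                    break
        return f"({','.join(parts)}){label}:{blen}"


# ---------------------------------------------------------------------------
# distances


def p_distance_matrix(
    msa: MultiAlignment, taxa: list[str] | None = None
) -> DistanceMatrix:
    """Uncorrected pairwise p-distances with pairwise deletion."""
    taxa = taxa or msa.isolates()
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    matrix = msa.char_matrix(taxa)
    return _p_distance_from_matrix(matrix, taxa)


def _p_distance_from_matrix(matrix: np.ndarray, taxa: list[str],
                            weights: np.ndarray | None = None) -> DistanceMatrix:
    n = len(taxa)
    unambig = np.isin(matrix, np.frombuffer(b"ACGT", dtype=np.uint8))
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = unambig[i] & unambig[j]
            diff = comparable & (matrix[i] != matrix[j])
            if weights is None:
                n_comp = int(comparable.sum())
                n_diff = int(diff.sum())
            else:
                n_comp = float(weights[comparable].sum())
                n_diff = float(weights[diff].sum())
            if n_comp == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            values[i, j] = values[j, i] = n_diff / n_comp
    return DistanceMatrix(taxa, values)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Classical Saitou–Nei neighbor joining.

    Ties in the Q criterion break by the lexicographic order of the
    (smallest-leaf-label) pair representatives; negative branch-length
    estimates are kept (clamping happens only at Newick output).
    """
    taxa = list(D.taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    tree = Tree(taxa)
    active: dict[int, str] = {i: taxa[i] for i in range(n)}  # node -> repr label
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = dist[(j, i)] = float(D.values[i, j])

    while len(active) > 3:
        nodes = sorted(active)
        m = len(nodes)
        totals = {
            a: sum(dist[(a, b)] for b in nodes if b != a) for a in nodes
        }
        best = None
        for a, b in itertools.combinations(nodes, 2):
            q = (m - 2) * dist[(a, b)] - totals[a] - totals[b]
            key = tuple(sorted((active[a], active[b])))
            if best is None or q < best[0] - 1e-12 or (
                abs(q - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (q, key, a, b)
        _, _, a, b = best
        new = tree.new_node()
        d_ab = dist[(a, b)]
        la = 0.5 * d_ab + (totals[a] - totals[b]) / (2 * (m - 2))
        lb = d_ab - la
        tree.link(a, new, la)
        tree.link(b, new, lb)
        for c in nodes:
            if c in (a, b):
                continue
            d_new = 0.5 * (dist[(a, c)] + dist[(b, c)] - d_ab)
            dist[(new, c)] = dist[(c, new)] = d_new
        active[new] = min(active[a], active[b])
        del active[a], active[b]

    a, b, c = sorted(active)
    center = tree.new_node()
    la = 0.5 * (dist[(a, b)] + dist[(a, c)] - dist[(b, c)])
    lb = 0.5 * (dist[(a, b)] + dist[(b, c)] - dist[(a, c)])
    lc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
    tree.link(a, center, la)
    tree.link(b, center, lb)
    tree.link(c, center, lc)
    return tree


# ---------------------------------------------------------------------------
# OLS branch lengths / minimum evolution


def ols_tree_length(tree: Tree, D: DistanceMatrix) -> tuple[dict, float]:
    """Ordinary-least-squares branch lengths for a fixed topology.

    Returns (edge -> length, tree length).  Negative estimates are kept in
    the sum, per the classical minimum-evolution criterion.
    """
    leaf_index = {label: i for i, label in enumerate(tree.labels)}
    if sorted(leaf_index) != sorted(D.taxa):
        raise ValueError("topology and distance matrix disagree on taxa")
    edges = tree.edges()
    edge_pos = {e: k for k, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(tree.n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        path = _edge_path(tree, i, j)
        for e in path:
            A[row, edge_pos[e]] = 1.0
        ti = D.taxa.index(tree.labels[i])
        tj = D.taxa.index(tree.labels[j])
        d[row] = D.values[ti, tj]
    lengths, *_ = np.linalg.lstsq(A, d, rcond=None)
    branch = {e: float(l) for e, l in zip(edges, lengths)}
    for (u, v), length in branch.items():
        tree.adj[u][v] = tree.adj[v][u] = length
    return branch, float(lengths.sum())


def _edge_path(tree: Tree, a: int, b: int) -> list[tuple[int, int]]:
    prev = {a: None}
    stack = [a]
    while stack:
        node = stack.pop()
        if node == b:
            break
        for nbr in tree.adj[node]:
            if nbr not in prev:
                prev[nbr] = node
                stack.append(nbr)
    path = []
    node = b
    while prev[node] is not None:
        parent = prev[node]
        path.append((min(node, parent), max(node, parent)))
        node = parent
    return path


def nni_neighbors(tree: Tree):
    """All nearest-neighbor-interchange rearrangements (2 per internal edge)."""
    for u, v in tree.internal_edges():
        u_nbrs = [x for x in tree.adj[u] if x != v]
        v_nbrs = [x for x in tree.adj[v] if x != u]
        b = u_nbrs[1]
        for c in v_nbrs:
            variant = tree.copy()
            lb = variant.adj[u][b]
            lc = variant.adj[v][c]
            variant.unlink(u, b)
            variant.unlink(v, c)
            variant.link(u, c, lc)
            variant.link(v, b, lb)
            yield variant


def me_search_cni(start: Tree, D: DistanceMatrix) -> Tree:
    """Minimum-evolution hill climb over the close-neighbor-interchange
    neighborhood.

    CNI examines every topology within topological distance 4 of the
    current tree — all single NNI rearrangements plus their NNI
    rearrangements — moves to the lowest OLS tree length
    (canonical-topology tie-break), and stops when no examined topology
    improves the criterion.  Deterministic.
    """
    current = start.copy()
    _, current_len = ols_tree_length(current, D)
    current_key = current.canonical_key()
    while True:
        best = None
        seen = {current_key}
        frontier = list(nni_neighbors(current))
        second = [n2 for n1 in frontier for n2 in nni_neighbors(n1)]
        for candidate in frontier + second:
            key = candidate.canonical_key()
            if key in seen:
                continue
            seen.add(key)
            _, cand_len = ols_tree_length(candidate, D)
            if best is None or cand_len < best[0] - 1e-12 or (
                abs(cand_len - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (cand_len, key, candidate)
        if best is None or best[0] >= current_len - 1e-12:
            return current
        current_len, current_key, current = best[0], best[1], best[2]


def enumerate_topologies(taxa: list[str]):
    """All unrooted binary topologies (stepwise leaf addition); 15 for 5 taxa."""
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    base = Tree(taxa)
    center = base.new_node()
    for leaf in range(3):
        base.link(leaf, center, 1.0)
    partial = [base]
    for leaf in range(3, len(taxa)):
        grown = []
        for tree in partial:
            for u, v in tree.edges():
                variant = tree.copy()
                mid = variant.new_node()
                length = variant.adj[u][v]
                variant.unlink(u, v)
                variant.link(u, mid, length / 2)
                variant.link(mid, v, length / 2)
                variant.link(leaf, mid, 1.0)
                grown.append(variant)
        partial = grown
    return partial


def exhaustive_me(D: DistanceMatrix) -> tuple[Tree, float]:
    """Global ME optimum by enumeration (small taxon sets only)."""
    best = None
    for tree in enumerate_topologies(D.taxa):
        _, length = ols_tree_length(tree, D)
        key = tree.canonical_key()
        if best is None or length < best[1] - 1e-12 or (
            abs(length - best[1]) <= 1e-12 and key < best[2]
        ):
            best = (tree, length, key)
    return best[0], best[1]


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    tree: Tree
    supports: dict[frozenset[str], float]
    n_reps: int


def _compress_columns(matrix: np.ndarray):
    patterns, counts = np.unique(matrix.T, axis=0, return_counts=True)
    return patterns.T.copy(), counts.astype(float)


def _me_tree_from_matrix(matrix, taxa, weights):
    D = _p_distance_from_matrix(matrix, taxa, weights)
    return me_search_cni(neighbor_joining(D), D)


def bootstrap_support(
    msa: MultiAlignment,
    taxa: list[str] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Column-resampling bootstrap of the distances -> NJ -> CNI pipeline.

    Support of each split in the point-estimate tree is the percentage of
    replicates whose ME tree contains it.  Deterministic given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa = taxa or msa.isolates()
    matrix = msa.char_matrix(taxa)
    patterns, counts = _compress_columns(matrix)
    total = counts.sum()

    point_tree = _me_tree_from_matrix(patterns, taxa, counts)
    point_splits = point_tree.splits()
    tally = {split: 0 for split in point_splits}

    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        weights = rng.multinomial(int(total), counts / total).astype(float)
        present = weights > 0
        rep_tree = _me_tree_from_matrix(
            patterns[:, present], taxa, weights[present]
        )
        for split in rep_tree.splits():
            if split in tally:
                tally[split] += 1
    supports = {split: 100.0 * k / n_reps for split, k in tally.items()}
    return BootstrapResult(point_tree, supports, n_reps)
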