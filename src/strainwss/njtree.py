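"""Cross-method check: genome-wide SNV p-distances, neighbor-joining tree
construction, and relatedness calls from leaf-to-leaf branch-length distance.

Distances are plain mismatch fractions over the same comparison set as the
windowed similarity (union of variant positions, implicit reference state
where adequately covered, unknowable positions excluded) — a monotone
stand-in for substitution-model distances, which is all the concordance
check needs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import TreeError
from .profile_io import SampleProfile
from .wss import DEFAULT_SITE_DEPTH_MIN, _pair_states

DEFAULT_BRANCH_THRESHOLD = 0.001

PairKey = tuple[str, str]


def pair_key(a: str, b: str) -> PairKey:
    return (a, b) if a <= b else (b, a)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal; NaN = missing entry
    (a pair with no comparable positions), rejected by tree building."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise TreeError(f"matrix shape {self.d.shape} != ({n},{n})")
        finite = np.isfinite(self.d)
        if not np.allclose(self.d[finite & finite.T], self.d.T[finite & finite.T]):
            raise TreeError("matrix is not symmetric")
        if not np.all(np.diag(self.d) == 0):
            raise TreeError("matrix diagonal must be zero")
        if np.any(self.d[finite] < 0):
            raise TreeError("negative distance")

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.d).any())


def snv_distance_matrix(
    profiles: Sequence[SampleProfile],
    site_depth_min: int = DEFAULT_SITE_DEPTH_MIN,
) -> DistanceMatrix:
    """Whole-genome p-distance between every pair of profiles."""
    if len(profiles) < 3:
        raise TreeError("need >= 3 profiles for a distance matrix")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise TreeError("duplicate sample ids")
    n = len(profiles)
    d = np.zeros((n, n), dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        _, sa, sb = _pair_states(profiles[i], profiles[j], site_depth_min)
        if sa.size == 0:
            d[i, j] = d[j, i] = np.nan
        else:
            d[i, j] = d[j, i] = float(np.count_nonzero(sa != sb)) / sa.size
    return DistanceMatrix(sample_ids=ids, d=d)


@dataclass
class NJTree:
    """Unrooted tree as an adjacency map; leaves labeled by sample id."""

    adjacency: dict[int, dict[int, float]]
    leaf_nodes: dict[str, int]

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_nodes)

    def path_distance(self, leaf_a: str, leaf_b: str) -> float:
        for name in (leaf_a, leaf_b):
            if name not in self.leaf_nodes:
                raise TreeError(f"unknown leaf {name!r}")
        if leaf_a == leaf_b:
            return 0.0
        start = self.leaf_nodes[leaf_a]
        goal = self.leaf_nodes[leaf_b]
        # iterative DFS on a tree: track cumulative length from start
        dist = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            if node == goal:
                return dist[node]
            for nbr, length in self.adjacency[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + length
                    stack.append(nbr)
        raise TreeError("disconnected tree")  # pragma: no cover

    def leaf_distance_matrix(self) -> DistanceMatrix:
        names = self.leaves
        n = len(names)
        d = np.zeros((n, n))
        for i, a in enumerate(names):
            dist = {self.leaf_nodes[a]: 0.0}
            stack = [self.leaf_nodes[a]]
            while stack:
                node = stack.pop()
                for nbr, length in self.adjacency[node].items():
                    if nbr not in dist:
                        dist[nbr] = dist[node] + length
                        stack.append(nbr)
            for j, b in enumerate(names):
                d[i, j] = dist[self.leaf_nodes[b]]
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(sample_ids=names, d=0.5 * (d + d.T))

    def to_newick(self) -> str:
        # root at the highest-numbered internal node (last join)
        internal = [n for n in self.adjacency if n not in self.leaf_nodes.values()]
        root = max(internal) if internal else next(iter(self.adjacency))
        names = {node: name for name, node in self.leaf_nodes.items()}

        def render(node: int, parent: int | None) -> str:
            children = [
                (nbr, length)
                for nbr, length in sorted(self.adjacency[node].items())
                if nbr != parent
            ]
            if not children:
                return names[node]
            inner = ",".join(
                f"{render(nbr, node)}:{length:.10g}" for nbr, length in children
            )
            return f"({inner})"

        return render(root, None) + ";"


def build_nj_tree(matrix: DistanceMatrix) -> NJTree:
    """Saitou–Nei neighbor joining with vectorized Q-matrix selection.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, preserving the pair's joint length.
    """
    n = len(matrix.sample_ids)
    if n < 3:
        raise TreeError("neighbor joining needs >= 3 taxa")
    if matrix.has_missing:
        raise TreeError("distance matrix has missing entries")

    D = matrix.d.copy()
    node_of = list(range(n))  # tree node id for each active row
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    next_node = n

    def connect(a: int, b: int, length: float) -> None:
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    while len(node_of) > 2:
        m = D.shape[0]
        r = D.sum(axis=1)
        q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_node
        next_node += 1
        connect(u, node_of[i], li)
        connect(u, node_of[j], lj)
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_new[: m - 2, m - 2] = du[keep]
        D_new[m - 2, : m - 2] = du[keep]
        D_new[m - 2, m - 2] = 0.0
        D = D_new
        node_of = [node_of[k] for k in keep] + [u]

    connect(node_of[0], node_of[1], max(D[0, 1], 0.0))
    leaf_nodes = {name: idx for idx, name in enumerate(matrix.sample_ids)}
    return NJTree(adjacency=adjacency, leaf_nodes=leaf_nodes)


def tree_relatedness(
    tree: NJTree,
    sample_a: str,
    sample_b: str,
    threshold: float = DEFAULT_BRANCH_THRESHOLD,
) -> str:
    """'related' iff the leaf-to-leaf path distance is strictly below
    ``threshold``; the default mirrors a small-branch-length criterion but
    the appropriate scale depends on the distance used."""
    return (
        "related"
        if tree.path_distance(sample_a, sample_b) < threshold
        else "unrelated"
    )


def method_agreement(
    wss_calls: Mapping[PairKey, str],
    tree_calls: Mapping[PairKey, str],
) -> tuple[float, dict[tuple[str, str], int]]:
    """Fraction of sample pairs on which the two methods give the same label,
    plus a (wss_label, tree_label) contingency of related/unrelated counts."""
    wss_keys = {pair_key(*k) for k in wss_calls}
    tree_keys = {pair_key(*k) for k in tree_calls}
    if wss_keys != tree_keys:
        missing = sorted(wss_keys ^ tree_keys)
        raise TreeError(f"pair sets differ between methods: {missing[:10]}")
    wss_norm = {pair_key(*k): v for k, v in wss_calls.items()}
    tree_norm = {pair_key(*k): v for k, v in tree_calls.items()}
    labels = ("related", "unrelated")
    contingency = {(a, b): 0 for a in labels for b in labels}
    matches = 0
    for key in wss_norm:
        a, b = wss_norm[key], tree_norm[key]
        if a == b:
            matches += 1
        if a in labels and b in labels:
            contingency[(a, b)] += 1
    return matches / len(wss_norm), contingency
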