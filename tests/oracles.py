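"""Independent reference implementations used only to check the package.

Everything here is deliberately written the slow, obvious way and shares no
code with strainwss internals.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde


def wss_bruteforce(
    profile_a,
    profile_b,
    window_size=1000,
    site_depth_min=5,
    low_frac=0.5,
    min_windows=1,
):
    """Whole-genome WSS recomputed position by position with plain loops."""
    length = profile_a.reference.length
    states_a = {pos: c.genotype_state for pos, c in profile_a.calls.items()}
    states_b = {pos: c.genotype_state for pos, c in profile_b.calls.items()}
    depth_a = profile_a.depth.depth
    depth_b = profile_b.depth.depth

    similarities = []
    start = 0
    while start < length:
        end = min(start + window_size, length)
        size = end - start
        low_a = sum(1 for i in range(start, end) if depth_a[i] < site_depth_min)
        low_b = sum(1 for i in range(start, end) if depth_b[i] < site_depth_min)
        if low_a > low_frac * size or low_b > low_frac * size:
            start = end
            continue
        compared = 0
        matched = 0
        for pos in range(start + 1, end + 1):
            a_has = pos in states_a
            b_has = pos in states_b
            if not a_has and not b_has:
                continue
            if not a_has and depth_a[pos - 1] < site_depth_min:
                continue
            if not b_has and depth_b[pos - 1] < site_depth_min:
                continue
            sa = states_a.get(pos, 0)
            sb = states_b.get(pos, 0)
            compared += 1
            if sa == sb:
                matched += 1
        if compared > 0:
            similarities.append(matched / compared)
        start = end
    if len(similarities) < min_windows:
        return None
    return sum(similarities) / len(similarities)


def kde_crossing_fine_grid(related, unrelated, grid_points=5120):
    """Density-crossing cutoff on a fine grid between the class means:
    the grid point minimizing |f_related - f_unrelated|, tie-broken toward
    the midpoint of the class means."""
    related = np.asarray(related, dtype=float)
    unrelated = np.asarray(unrelated, dtype=float)
    kde_r = gaussian_kde(related, bw_method="silverman")
    kde_u = gaussian_kde(unrelated, bw_method="silverman")
    lo = min(related.mean(), unrelated.mean())
    hi = max(related.mean(), unrelated.mean())
    grid = np.linspace(lo, hi, grid_points)
    gap = np.abs(kde_r(grid) - kde_u(grid))
    midpoint = 0.5 * (lo + hi)
    order = sorted(range(grid_points), key=lambda i: (gap[i], abs(grid[i] - midpoint)))
    return float(grid[order[0]])


def random_additive_tree(n_leaves, rng):
    """Random binary tree with uniform branch lengths; returns the leaf
    names and the leaf-to-leaf distance matrix implied by path summation."""
    assert n_leaves >= 3
    adjacency = {}

    def connect(a, b, length):
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    def blen():
        return float(rng.uniform(0.05, 1.0))

    # star on the first three leaves, then split random edges
    connect("hub0", "L0", blen())
    connect("hub0", "L1", blen())
    connect("hub0", "L2", blen())
    n_internal = 1
    edges = [("hub0", "L0"), ("hub0", "L1"), ("hub0", "L2")]
    for k in range(3, n_leaves):
        a, b = edges[rng.integers(0, len(edges))]
        length = adjacency[a].pop(b)
        adjacency[b].pop(a)
        edges.remove((a, b))
        hub = f"hub{n_internal}"
        n_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        connect(a, hub, length * split)
        connect(hub, b, length * (1 - split))
        leaf = f"L{k}"
        connect(hub, leaf, blen())
        edges.extend([(a, hub), (hub, b), (hub, leaf)])

    names = [f"L{i}" for i in range(n_leaves)]
    dist = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(names):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, length in adjacency[node].items():
                if nbr not in seen:
                    seen[nbr] = seen[node] + length
                    stack.append(nbr)
        for j, dst in enumerate(names):
            dist[i, j] = seen[dst]
    np.fill_diagonal(dist, 0.0)
    return names, 0.5 * (dist + dist.T)


def grouped_unrelated_individual_counts(calls):
    """Independent recount for unrelated_count_matrix: distinct individuals
    with at least one unrelated call, per (dataset, species)."""
    groups = {}
    for c in calls:
        if c.label == "unrelated":
            groups.setdefault((c.dataset_id, c.species_id), set()).add(c.individual_id)
    return {key: len(inds) for key, inds in groups.items()}
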