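"""Independent brute-force reference implementations used as oracles.

Deliberately written with different algorithms and data structures than the
package (dense O(n^2) distance matrices, recursive union-find) so that
agreement is meaningful.
"""

import numpy as np


def minimum_image_matrix(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    n = len(points)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            delta = points[i] - points[j]
            delta = delta - box * np.round(delta / box)
            dist[i, j] = dist[j, i] = np.sqrt(np.sum(delta**2))
    return dist


def dbscan_reference(points: np.ndarray, box: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """O(n^2) DBSCAN with union-find over core points.

    Same conventions as the implementation under test: neighborhoods include
    the point itself; border points join the adjacent cluster with the
    smallest id; cluster ids ordered by smallest core-point index.
    """
    n = len(points)
    dist = minimum_image_matrix(points, box)
    adj = dist <= eps
    is_core = adj.sum(axis=1) >= min_pts

    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    core_idx = np.flatnonzero(is_core)
    for i in core_idx:
        for j in core_idx:
            if j > i and adj[i, j]:
                union(i, j)

    root_to_label: dict[int, int] = {}
    labels = np.full(n, -1, dtype=int)
    for i in core_idx:  # ascending: label order matches smallest core index
        root = find(i)
        if root not in root_to_label:
            root_to_label[root] = len(root_to_label)
        labels[i] = root_to_label[root]

    for i in range(n):
        if is_core[i]:
            continue
        neighbor_labels = [labels[j] for j in np.flatnonzero(adj[i]) if is_core[j]]
        if neighbor_labels:
            labels[i] = min(neighbor_labels)
    return labels


def partition_signature(labels: np.ndarray) -> tuple:
    """Canonical partition: noise set + frozenset of clusters."""
    labels = np.asarray(labels)
    clusters = frozenset(
        frozenset(np.flatnonzero(labels == lab).tolist())
        for lab in np.unique(labels) if lab >= 0
    )
    noise = frozenset(np.flatnonzero(labels == -1).tolist())
    return noise, clusters


def contact_counts_reference(
    prot_pos: np.ndarray, lip_pos: np.ndarray, box: np.ndarray, cutoff: float
) -> np.ndarray:
    """All-pairs contact indicator matrix (n_prot, n_lip)."""
    out = np.zeros((len(prot_pos), len(lip_pos)), dtype=bool)
    for i, p in enumerate(prot_pos):
        delta = lip_pos - p
        delta = delta - box * np.round(delta / box)
        out[i] = np.sqrt((delta**2).sum(axis=1)) <= cutoff
    return out


def rmsd_grid_search(coords: np.ndarray, reference: np.ndarray, n_grid: int = 40) -> float:
    """Brute-force rigid superposition: scan Euler angles, refine locally."""
    from scipy.spatial.transform import Rotation

    a = coords - coords.mean(axis=0)
    b = reference - reference.mean(axis=0)

    def value(angles):
        r = Rotation.from_euler("zyx", angles)
        return np.sqrt(np.mean(np.sum((r.apply(a) - b) ** 2, axis=1)))

    grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    best, best_angles = np.inf, None
    for az in grid:
        for ay in grid[: n_grid // 2]:
            for ax in grid:
                v = value((az, ay, ax))
                if v < best:
                    best, best_angles = v, (az, ay, ax)
    from scipy.optimize import minimize

    res = minimize(value, best_angles, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
    return float(min(best, res.fun))
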