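"""Minimum-image utilities for orthorhombic periodic boxes.

All distances are Euclidean after wrapping each Cartesian component into
``[-L/2, L/2)``.  Only rectangular boxes are supported; triclinic cells are
out of scope for the monolayer geometries handled here.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "minimum_image",
    "minimum_image_distance",
    "wrap_positions",
    "pair_distance_matrix",
    "neighbor_lists",
]


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Parameters
    ----------
    delta:
        Displacement vectors, shape ``(..., d)``.
    box:
        Box edge lengths, shape ``(d,)``.
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distance between points ``a`` and ``b`` (broadcasting)."""
    return np.linalg.norm(minimum_image(np.asarray(a) - np.asarray(b), box), axis=-1)


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into ``[0, L)`` per axis."""
    box = np.asarray(box, dtype=float)
    return np.mod(np.asarray(positions, dtype=float), box)


def pair_distance_matrix(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Dense all-pairs minimum-image distance matrix, O(n^2) memory."""
    points = np.asarray(points, dtype=float)
    delta = points[:, None, :] - points[None, :, :]
    return np.linalg.norm(minimum_image(delta, box), axis=-1)


def _check_eps(eps: float, box: np.ndarray) -> None:
    box = np.asarray(box, dtype=float)
    if eps >= float(np.min(box)) / 2.0:
        raise ValueError(
            f"search radius {eps} is ambiguous under the minimum-image convention "
            f"for box {tuple(box)}: it must be < min(box)/2 = {np.min(box) / 2.0}"
        )


def neighbor_lists(points: np.ndarray, box: np.ndarray, eps: float) -> list[np.ndarray]:
    """Per-point neighbor index lists within ``eps`` (periodic, self included).

    Uses a k-d tree with periodic topology; coordinates are wrapped into the
    primary cell first, as required by the tree.
    """
    _check_eps(eps, box)
    pts = wrap_positions(points, box)
    tree = cKDTree(pts, boxsize=np.asarray(box, dtype=float))
    lists = tree.query_ball_point(pts, r=eps)
    return [np.asarray(sorted(nb), dtype=np.intp) for nb in lists]
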