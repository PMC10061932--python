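"""Least-squares rigid superposition (Kabsch) and RMSD."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["rmsd", "superpose"]


def superpose(coords: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimally superpose ``coords`` onto ``reference``.

    Returns the transformed coordinates and the post-fit RMSD (same length
    unit as the input).  Uses the Kabsch solution via quaternion alignment.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if coords.shape != reference.shape or coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords and reference must both have shape (n, 3)")
    if coords.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    c_mean = coords.mean(axis=0)
    r_mean = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - r_mean, coords - c_mean)
    moved = rot.apply(coords - c_mean) + r_mean
    return moved, float(rssd / np.sqrt(coords.shape[0]))


def rmsd(coords: np.ndarray, reference: np.ndarray, superpose_first: bool = True) -> float:
    """RMSD between matched point sets, after optimal rigid fit by default."""
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if coords.shape != reference.shape:
        raise ValueError("coords and reference must have identical shapes")
    if superpose_first:
        _, value = superpose(coords, reference)
        return value
    return float(np.sqrt(np.mean(np.sum((coords - reference) ** 2, axis=1))))
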