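"""Acyl-chain and protein tilt relative to the outward monolayer normal.

Angles are reported in degrees in [0, 180]: 0 means pointing straight out of
the interface along the leaflet's outward normal (+z upper, -z lower), 90
lies in the monolayer plane, and > 90 points back toward the water.  Chain
tilt uses the first->last chain-carbon vector; the protein axis is the
principal component of its backbone coordinates, oriented from the
N terminus to the C terminus.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .topology import Frame, Topology

__all__ = ["angle_to_normal", "chain_tilt", "protein_axis_tilt"]

logger = logging.getLogger(__name__)


def angle_to_normal(vectors: np.ndarray, outward_sign: float | np.ndarray) -> np.ndarray:
    """Angle (deg) between vectors and the outward normal (sign * +z)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length vector has no tilt angle")
    cosang = np.clip(np.asarray(outward_sign) * vectors[:, 2] / norms, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def chain_tilt(
    frame: Frame,
    topology: Topology,
    chain_ends: dict[str, list[tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """Per-chain tilt angles.

    ``chain_ends`` maps residue name to (first_carbon, last_carbon) atom-name
    pairs, one per chain; by default it is derived from the role
    configuration used at role assignment time via CHARMM36 names.  Chains
    whose end atoms are missing are skipped (count logged).

    Returns a tidy table: ``mol_id``, ``lipid_type``, ``leaflet``,
    ``chain``, ``angle`` (deg), ``x``, ``y`` (chain midpoint, for
    distance-to-protein grouping downstream).
    """
    if chain_ends is None:
        from .topology import DEFAULT_ROLE_CONFIG

        chain_ends = {
            resname: list(zip(entry.chain_starts, entry.chain_ends))
            for resname, entry in DEFAULT_ROLE_CONFIG.items()
            if entry.chain_starts
        }

    leaflet = topology.atom_leaflet()
    types = topology.atom_lipid_type()
    rows = []
    skipped = 0
    mids = topology.mol_ids()
    mol_index = topology.mol_index()
    for i, mid in enumerate(mids):
        sel = mol_index == i
        resname = topology.resname[sel][0]
        if resname not in chain_ends:
            continue
        names = topology.atom_name[sel]
        pos = frame.positions[sel]
        side = leaflet[sel][0]
        sign = 1.0 if side == "upper" else -1.0
        for c, (first, last) in enumerate(chain_ends[resname]):
            i_first = np.flatnonzero(names == first)
            i_last = np.flatnonzero(names == last)
            if i_first.size != 1 or i_last.size != 1:
                skipped += 1
                continue
            vec = pos[i_last[0]] - pos[i_first[0]]
            mid_xy = 0.5 * (pos[i_last[0], :2] + pos[i_first[0], :2])
            rows.append(
                {
                    "mol_id": mid,
                    "lipid_type": types[sel][0],
                    "leaflet": side,
                    "chain": c,
                    "angle": float(angle_to_normal(vec, sign)[0]),
                    "x": mid_xy[0],
                    "y": mid_xy[1],
                }
            )
    if skipped:
        logger.info("chain_tilt: skipped %d chains with missing end atoms", skipped)
    return pd.DataFrame.from_records(rows)


def protein_axis_tilt(
    backbone_xyz: np.ndarray,
    outward_sign: float = 1.0,
) -> float:
    """Tilt of the protein principal axis vs the outward monolayer normal.

    The axis is the largest-variance principal component of the centered
    backbone coordinates, with its sign fixed to run from the N terminus
    (first point) to the C terminus (last point).  Two points degenerate to
    their connecting vector; fewer than two are an error.
    """
    pts = np.asarray(backbone_xyz, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("backbone must be an (n >= 2, 3) coordinate array")
    if pts.shape[0] == 2:
        axis = pts[1] - pts[0]
    else:
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        if np.dot(axis, pts[-1] - pts[0]) < 0:
            axis = -axis
    return float(angle_to_normal(axis, outward_sign)[0])
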