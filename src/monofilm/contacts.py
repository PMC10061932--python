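"""Lipid–protein contact analysis.

A contact is one (protein heavy atom, lipid heavy atom) pair within a 3D
minimum-image distance cutoff (0.3 nm by default).  Raw counts are summed
per protein residue and lipid type and then normalized by the number of
possible contact partners — the heavy-atom abundance of each lipid type in
the protein-containing leaflet — so that a small, scarce lipid competing
with an abundant one can still show up as a preferred partner.  Per-residue
preference maps are additionally corrected for lipid-type mole fraction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pbc import wrap_positions
from .topology import Frame, Topology

__all__ = [
    "DEFAULT_CUTOFF",
    "count_contacts",
    "normalize_contacts",
    "contact_preference",
    "stratify_by_regime",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.3  # nm, heavy-atom pairs


def count_contacts(
    frame: Frame,
    topology: Topology,
    cutoff: float = DEFAULT_CUTOFF,
    include_types: tuple[str, ...] = ("DPPC", "POPC", "POPG", "CHOL"),
) -> pd.DataFrame:
    """Raw heavy-atom contact counts per (protein residue, lipid type).

    Uses a periodic k-d tree; the result is exactly the brute-force all-pairs
    count (the tree only accelerates the search).  Returns a tidy table:
    ``residue_id``, ``residue_name``, ``lipid_type``, ``contacts``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    box = frame.box
    if cutoff >= float(box.min()) / 2.0:
        raise ValueError(
            f"cutoff {cutoff} nm is ambiguous under minimum image for box {tuple(box)}"
        )

    prot_mask = topology.role_mask("protein")
    if not prot_mask.any():
        raise ValueError("no protein heavy atoms tagged; nothing to count contacts against")
    types = topology.atom_lipid_type()
    lipid_mask = topology.is_heavy & np.isin(types, include_types)

    prot_idx = np.flatnonzero(prot_mask)
    lip_idx = np.flatnonzero(lipid_mask)
    prot_pos = wrap_positions(frame.positions[prot_idx], box)
    lip_pos = wrap_positions(frame.positions[lip_idx], box)

    tree = cKDTree(lip_pos, boxsize=box)
    neighbor_lists = cKDTree(prot_pos, boxsize=box).query_ball_tree(tree, r=cutoff)

    counts: dict[tuple[int, str, str], int] = {}
    for pi, lips in zip(prot_idx, neighbor_lists):
        if not lips:
            continue
        rid = int(topology.mol_id[pi])
        rname = str(topology.resname[pi])
        for lj in lips:
            ltype = str(types[lip_idx[lj]])
            key = (rid, rname, ltype)
            counts[key] = counts.get(key, 0) + 1

    rows = [
        {"residue_id": rid, "residue_name": rname, "lipid_type": ltype, "contacts": n}
        for (rid, rname, ltype), n in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["residue_id", "residue_name", "lipid_type", "contacts"]
    )


def _heavy_abundance(topology: Topology, leaflet: str | None) -> pd.Series:
    """Heavy-atom count per lipid type, optionally restricted to one leaflet."""
    types = topology.atom_lipid_type()
    mask = topology.is_heavy & (types != "PROTEIN") & (types != None)  # noqa: E711
    if leaflet is not None:
        mask &= topology.atom_leaflet() == leaflet
    return pd.Series(types[mask]).value_counts()


def _mole_fraction(topology: Topology, leaflet: str | None) -> pd.Series:
    mids = topology.mol_ids()
    mtypes = topology.mol_type
    keep = mtypes != "PROTEIN"
    if leaflet is not None and topology.leaflet is not None:
        keep &= topology.leaflet == leaflet
    counts = pd.Series(mtypes[keep]).value_counts()
    return counts / counts.sum()


def normalize_contacts(
    raw: pd.DataFrame,
    topology: Topology,
    leaflet: str | None = None,
) -> pd.DataFrame:
    """Normalize raw counts by the number of possible contact partners.

    ``normalized = contacts / heavy-atom abundance`` of the lipid type in the
    protein's leaflet (pass ``leaflet=None`` to use both).  The per-residue
    rows additionally carry ``normalized_per_residue``, further divided by
    the lipid-type mole fraction, for residue-resolved preference maps.
    Types absent from the leaflet get missing values rather than infinities.
    """
    abundance = _heavy_abundance(topology, leaflet)
    molefrac = _mole_fraction(topology, leaflet)
    out = raw.copy()
    ab = out["lipid_type"].map(abundance)
    mf = out["lipid_type"].map(molefrac)
    out["normalized"] = out["contacts"] / ab
    out["normalized_per_residue"] = out["normalized"] / mf
    missing = ab.isna()
    if missing.any():
        logger.warning(
            "normalize_contacts: %d rows reference lipid types absent from the "
            "leaflet; reported as missing",
            int(missing.sum()),
        )
    return out


def contact_preference(normalized: pd.DataFrame) -> pd.Series:
    """Per lipid type, summed normalized contacts over all residues."""
    return normalized.groupby("lipid_type")["normalized"].sum()


def stratify_by_regime(
    per_frame_tables: list[pd.DataFrame],
    regime_per_frame: np.ndarray,
    replica_per_frame: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aggregate per-frame contact tables by surface-pressure regime.

    Frames outside every regime (label ``None``) are dropped with a logged
    count.  Within a regime the mean over frames is taken per
    (residue, lipid type); with replica labels the mean is taken per replica
    first and the standard error across replicas is attached (monolayers are
    the independent samples, frames are not).
    """
    regime_per_frame = np.asarray(regime_per_frame, dtype=object)
    if len(per_frame_tables) != regime_per_frame.size:
        raise ValueError("one regime label per frame table is required")
    dropped = int(sum(r is None for r in regime_per_frame))
    if dropped:
        logger.info("stratify_by_regime: dropped %d frames outside all regimes", dropped)

    pieces = []
    for i, (table, regime) in enumerate(zip(per_frame_tables, regime_per_frame)):
        if regime is None:
            continue
        piece = table.copy()
        piece["regime"] = str(regime)
        piece["frame"] = i
        piece["replica"] = replica_per_frame[i] if replica_per_frame is not None else 0
        pieces.append(piece)
    if not pieces:
        raise ValueError("no frames fell inside any regime")
    pooled = pd.concat(pieces, ignore_index=True)

    value_cols = [
        c for c in ("contacts", "normalized", "normalized_per_residue") if c in pooled.columns
    ]
    keys = ["regime", "residue_id", "residue_name", "lipid_type"]

    # per replica: mean over that replica's frames (absent pairs count as 0)
    n_frames = (
        pooled.groupby(["regime", "replica"])["frame"].nunique().rename("n_frames")
    )
    per_replica = (
        pooled.groupby(keys + ["replica"])[value_cols].sum().reset_index()
    )
    per_replica = per_replica.join(n_frames, on=["regime", "replica"])
    for c in value_cols:
        per_replica[c] = per_replica[c] / per_replica["n_frames"]

    agg = per_replica.groupby(keys)[value_cols].agg(["mean", "std", "count"])
    out = pd.DataFrame(index=agg.index)
    for c in value_cols:
        out[c] = agg[(c, "mean")]
        n_rep = agg[(c, "count")]
        sd = agg[(c, "std")]
        out[f"{c}_se"] = np.where(n_rep >= 2, sd / np.sqrt(n_rep), np.nan)
    return out.reset_index()
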