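"""Transverse (z) density profiles aligned on the phosphate plane.

Profiles answer where each molecular species sits relative to the air–water
interface and how thick the film is.  Per frame and leaflet, atom depths are
re-expressed as

    z' = -(s) * (z - <z_P>_leaflet)

where ``<z_P>`` is that leaflet's mean phosphorus z and ``s`` is the leaflet's
outward normal sign, so the acyl-chain (air) side is negative for both
leaflets and the phosphorus plane is exactly at z' = 0 in every frame.
Mass-weighted histograms are accumulated per species, averaged within
surface-pressure regimes, and summarized by *extent curves*: the outermost
positions where the profile first/last exceeds 5% of its maximum.  The
pooled phospholipid extent span is the monolayer thickness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import Frame, Topology

__all__ = ["DensityMap", "density_profile", "extent_5pct", "monolayer_thickness"]

logger = logging.getLogger(__name__)

#: amu/nm^3 -> kg/m^3
_AMU_PER_NM3 = 1.66053906660

EXTENT_THRESHOLD = 0.05


@dataclass
class DensityMap:
    """Regime-stratified transverse density profiles.

    ``profiles[regime][species]`` is the mean mass density (kg/m^3) on
    ``z_centers`` (nm, phosphate plane at 0, chain side negative);
    ``extents[regime][species]`` the (z_low, z_high) 5%-of-maximum extent.
    """

    z_edges: np.ndarray
    profiles: dict = field(default_factory=dict)
    extents: dict = field(default_factory=dict)
    n_frames: dict = field(default_factory=dict)

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.z_edges[1] - self.z_edges[0])

    def to_table(self) -> pd.DataFrame:
        rows = []
        for regime, by_species in self.profiles.items():
            for species, dens in by_species.items():
                for z, rho in zip(self.z_centers, dens):
                    rows.append(
                        {"regime": regime, "species": species, "z": z, "density": rho}
                    )
        return pd.DataFrame.from_records(rows)

    def extents_table(self) -> pd.DataFrame:
        rows = []
        for regime, by_species in self.extents.items():
            for species, (lo, hi) in by_species.items():
                rows.append(
                    {"regime": regime, "species": species, "z_low": lo, "z_high": hi}
                )
        return pd.DataFrame.from_records(rows)


def extent_5pct(z_centers: np.ndarray, density: np.ndarray) -> tuple[float, float]:
    """Outermost bin centers where density exceeds 5% of its maximum."""
    density = np.asarray(density, dtype=float)
    if density.size == 0 or np.all(density <= 0):
        raise ValueError("cannot compute extent of an empty density profile")
    above = density > EXTENT_THRESHOLD * density.max()
    idx = np.flatnonzero(above)
    return float(z_centers[idx[0]]), float(z_centers[idx[-1]])


def _aligned_depth(frame: Frame, topology: Topology) -> np.ndarray:
    """Per-atom phosphate-aligned depth z' (chain side negative)."""
    z = frame.positions[:, 2]
    p_mask = topology.role_mask("phosphorus")
    leaflet = topology.atom_leaflet()
    zp = np.empty_like(z)
    for side in ("upper", "lower"):
        in_leaflet = leaflet == side
        p_in = p_mask & in_leaflet
        if not p_in.any():
            raise ValueError(f"leaflet {side!r} has no phosphorus atoms to align on")
        ref = z[p_in].mean()
        # outward normal: +z for the upper leaflet, -z for the lower; the
        # chain region lies outward of the phosphate plane
        sign = 1.0 if side == "upper" else -1.0
        zp[in_leaflet] = -sign * (z[in_leaflet] - ref)
    return zp


def default_species_selector(topology: Topology) -> dict[str, np.ndarray]:
    """Standard species masks: phospholipid, CHOL, protein (heavy atoms)."""
    types = topology.atom_lipid_type()
    heavy = topology.is_heavy
    masks = {
        "phospholipid": heavy & np.isin(types, ("DPPC", "POPC", "POPG")),
        "CHOL": heavy & (types == "CHOL"),
        "protein": heavy & (types == "PROTEIN"),
    }
    return {k: v for k, v in masks.items()}


def density_profile(
    frames,
    topology: Topology,
    species_selector: dict[str, np.ndarray] | None = None,
    z_edges: np.ndarray | None = None,
    pressure_per_frame: np.ndarray | None = None,
    regimes_per_frame: np.ndarray | None = None,
) -> DensityMap:
    """Mass density vs phosphate-aligned depth, stratified by pressure regime.

    Parameters
    ----------
    frames:
        Iterable of :class:`Frame` sharing ``topology``.
    species_selector:
        Mapping species name -> boolean atom mask; defaults to
        phospholipid / CHOL / protein heavy atoms.
    z_edges:
        Histogram bin edges in nm (default: 0.1 nm bins over [-5, 3]).
    regimes_per_frame:
        Regime label per frame (e.g. from the isotherm window containing the
        frame); frames labeled ``None`` are dropped.  When omitted, all
        frames pool into the regime ``"all"``.
    pressure_per_frame:
        Unbinned alternative: pass Pi values and pre-computed labels via
        :func:`monofilm.isotherm.regime_of` instead; kept for convenience.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    if z_edges is None:
        z_edges = np.arange(-5.0, 3.0 + 1e-9, 0.1)
    z_edges = np.asarray(z_edges, dtype=float)

    if regimes_per_frame is None:
        if pressure_per_frame is not None:
            from .isotherm import regime_of

            regimes_per_frame = regime_of(np.asarray(pressure_per_frame))
        else:
            regimes_per_frame = np.array(["all"] * len(frames), dtype=object)
    regimes_per_frame = np.asarray(regimes_per_frame, dtype=object)
    if regimes_per_frame.size != len(frames):
        raise ValueError("regimes_per_frame must align with frames")

    if species_selector is None:
        species_selector = default_species_selector(topology)
    masses = topology.masses()

    empty = [name for name, mask in species_selector.items() if not np.asarray(mask).any()]
    for name in empty:
        logger.warning("species %r selects no atoms; skipped", name)
    selector = {k: np.asarray(v, dtype=bool) for k, v in species_selector.items() if k not in empty}

    acc: dict[str, dict[str, np.ndarray]] = {}
    n_frames: dict[str, int] = {}
    for frame, regime in zip(frames, regimes_per_frame):
        if regime is None:
            continue
        regime = str(regime)
        zp = _aligned_depth(frame, topology)
        # both leaflets share the aligned axis; volume per bin uses the full
        # interfacial area of the two monolayers
        area = 2.0 * frame.box[0] * frame.box[1]
        width = np.diff(z_edges)
        bucket = acc.setdefault(regime, {})
        n_frames[regime] = n_frames.get(regime, 0) + 1
        for name, mask in selector.items():
            hist, _ = np.histogram(zp[mask], bins=z_edges, weights=masses[mask])
            rho = _AMU_PER_NM3 * hist / (area * width)  # kg/m^3
            bucket[name] = bucket.get(name, 0.0) + rho

    if not acc:
        raise ValueError("no frames fell inside any pressure regime")

    dmap = DensityMap(z_edges=z_edges)
    for regime, bucket in acc.items():
        dmap.profiles[regime] = {k: v / n_frames[regime] for k, v in bucket.items()}
        dmap.n_frames[regime] = n_frames[regime]
        dmap.extents[regime] = {}
        for name, dens in dmap.profiles[regime].items():
            if np.all(dens <= 0):
                continue
            dmap.extents[regime][name] = extent_5pct(dmap.z_centers, dens)
    return dmap


def monolayer_thickness(density_map: DensityMap, species: str = "phospholipid") -> pd.DataFrame:
    """Thickness (nm) per pressure regime from the 5% extent of one species."""
    rows = []
    for regime, by_species in density_map.extents.items():
        if species not in by_species:
            raise ValueError(f"species {species!r} has no density extent in regime {regime!r}")
        lo, hi = by_species[species]
        rows.append({"regime": regime, "thickness": hi - lo, "z_low": lo, "z_high": hi})
    return pd.DataFrame.from_records(rows)
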