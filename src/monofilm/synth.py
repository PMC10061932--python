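"""Synthetic monolayer configurations with planted ground truth.

Every analysis stage in this package is validated against constructions
whose answer is known exactly:

* :func:`generate_monolayer` builds a two-leaflet monolayer of
  DPPC/POPC/POPG/CHOL (60/20/10/10 by default) in which a chosen fraction
  of the chain markers sits on hexagonal lattice patches (the condensed
  L_c phase) while the rest is placed as blue noise with a guaranteed
  minimum spacing that DBSCAN cannot cluster (the expanded L_e phase).
  An optional pseudo-protein disc carves an L_e halo of tunable width and
  strength.  True phase labels are returned with the configuration.
* :func:`generate_brownian` produces free 2D Brownian tracks with known D,
  wrapped into the box, keeping the unwrapped coordinates as ground truth.
* :func:`generate_pressure_series` plants an exact surface-tension
  schedule in the pressure-tensor components, optionally with Gaussian
  noise, together with a compression ramp of the area per lipid.
* :func:`generate_compression_stack` chains monolayer configurations over
  an APL grid with a planted condensed-fraction-vs-area relationship.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pbc import minimum_image
from .topology import (
    Frame,
    PressureSeries,
    ResidueRoles,
    Topology,
    Trajectory,
    assign_leaflets,
    assign_roles,
)

__all__ = [
    "ProteinSpec",
    "MonolayerSpec",
    "BrownianSpec",
    "MonolayerTruth",
    "generate_monolayer",
    "generate_brownian",
    "generate_pressure_series",
    "generate_compression_stack",
    "TRACER_ROLE_CONFIG",
]

DEFAULT_COMPOSITION = {"DPPC": 0.6, "POPC": 0.2, "POPG": 0.1, "CHOL": 0.1}

_PROTEIN_RESIDUE_CYCLE = (
    "LEU", "VAL", "ALA", "PHE", "LYS", "ARG", "GLY", "SER", "ILE", "PRO",
)

#: role config for single-atom Brownian tracer particles
TRACER_ROLE_CONFIG = {"DPPC": ResidueRoles("DPPC", "P", (), (), (), "P")}


class GeometryError(ValueError):
    """Requested packing cannot be realized at the given area per lipid."""


@dataclass(frozen=True)
class ProteinSpec:
    """Pseudo-protein: a rigid two-layer disc of beads.

    No attempt is made to mimic a real surfactant-protein structure; the
    analyses only need heavy-atom positions and residue identities.
    """

    radius: float = 1.2  # nm
    n_beads: int = 100
    halo_width: float = 1.5  # nm, L_e halo measured from the nearest bead
    halo_lc_suppression: float = 1.0  # probability a lattice site in the halo is demoted
    residue_names: tuple[str, ...] = _PROTEIN_RESIDUE_CYCLE

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.n_beads < 3:
            raise ValueError("protein disc needs radius > 0 and >= 3 beads")
        if self.halo_width < 0 or not 0 <= self.halo_lc_suppression <= 1:
            raise ValueError("halo parameters must be nonnegative (suppression in [0,1])")


@dataclass(frozen=True)
class ZModel:
    """Transverse placement model: per-role offsets from the interface (nm).

    Offsets are measured along the outward normal; phosphorus scatters about
    the interface plane with ``phosphorus_sigma`` while chain markers sit
    ``marker_offset`` into the chain region, matching the qualitative
    layering of a compressed monolayer.
    """

    phosphorus_sigma: float = 0.15
    marker_offset: float = 1.0
    marker_sigma: float = 0.05
    glycerol_offset: float = 0.2
    chain_start_offset: float = 0.45
    chain_end_offset: float = 1.6


@dataclass(frozen=True)
class MonolayerSpec:
    n_lipids_per_leaflet: int = 400
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    apl: float = 60.0  # Å²
    f_lc: float = 0.0  # planted condensed chain fraction
    lattice_spacing: float = 0.48  # nm, hexagonal spacing inside L_c patches
    patch_count: int = 3
    le_min_distance: float = 0.55  # nm, guaranteed spacing of expanded markers
    protein: ProteinSpec | None = None
    z_model: ZModel = field(default_factory=ZModel)
    box_height: float = 15.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"composition fractions must sum to 1, got {total}")
        if self.apl <= 0 or self.lattice_spacing <= 0:
            raise ValueError("apl and lattice_spacing must be positive")
        if not 0 <= self.f_lc <= 1:
            raise ValueError("f_lc must lie in [0, 1]")
        if self.n_lipids_per_leaflet < 4:
            raise ValueError("need at least 4 lipids per leaflet")


@dataclass(frozen=True)
class BrownianSpec:
    D_true: float = 0.05  # nm^2/ns
    n_particles: int = 100
    dt: float = 1.0  # ns
    n_steps: int = 100
    box_xy: float = 30.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_true < 0:
            raise ValueError("D_true must be nonnegative")
        if self.dt <= 0 or self.n_steps < 1 or self.n_particles < 1:
            raise ValueError("dt, n_steps and n_particles must be positive")


@dataclass
class MonolayerTruth:
    """Ground truth emitted with every generated monolayer."""

    markers: pd.DataFrame  # leaflet, mol_id, atom_name, x, y, phase
    f_lc_target: float
    protein_xy: dict  # leaflet -> (n_beads, 2) array (empty dict if none)

    def lc_fraction(self, leaflet: str | None = None) -> float:
        m = self.markers if leaflet is None else self.markers[self.markers.leaflet == leaflet]
        return float((m["phase"] == "Lc").mean())


# ---------------------------------------------------------------------------
# lattice helpers


def _hex_lattice(spacing: float, radius: float) -> np.ndarray:
    """Hexagonal lattice points covering a disc of the given radius (origin-centered)."""
    ny = int(math.ceil(radius / (spacing * math.sqrt(3) / 2))) + 2
    nx = int(math.ceil(radius / spacing)) + 2
    pts = []
    for j in range(-ny, ny + 1):
        y = j * spacing * math.sqrt(3) / 2
        off = (j % 2) * spacing / 2
        for i in range(-nx, nx + 1):
            pts.append((i * spacing + off, y))
    pts = np.asarray(pts)
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def _min_dist_to(points: np.ndarray, refs: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    if refs.size == 0:
        return np.full(len(points), np.inf)
    delta = minimum_image(points[:, None, :] - refs[None, :, :], box_xy)
    return np.linalg.norm(delta, axis=-1).min(axis=1)


def _protein_beads(spec: ProteinSpec, center_xy: np.ndarray, z0: float, sign: float) -> np.ndarray:
    """Sunflower-spiral beads on a two-layer disc (deterministic)."""
    n = spec.n_beads
    golden = math.pi * (3.0 - math.sqrt(5.0))
    k = np.arange(n)
    r = spec.radius * np.sqrt((k + 0.5) / n)
    theta = k * golden
    x = center_xy[0] + r * np.cos(theta)
    y = center_xy[1] + r * np.sin(theta)
    z = z0 + sign * np.where(k % 2 == 0, 0.2, 0.8)
    return np.column_stack([x, y, z])


def _largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: v * n for k, v in fractions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _try_place_centers(
    rng: np.random.Generator,
    radii: list[float],
    clearance: float,
    box_xy: np.ndarray,
) -> list[np.ndarray] | None:
    centers: list[np.ndarray] = []
    for r in radii:
        for _ in range(500):
            c = rng.uniform(0, box_xy, size=2)
            if all(
                np.linalg.norm(minimum_image(c - c2, box_xy)) > r + r2 + clearance
                for c2, r2 in zip(centers, radii[: len(centers)])
            ):
                centers.append(c)
                break
        else:
            return None
    return centers


def _place_patches(
    rng: np.random.Generator,
    n_sites: int,
    patch_count: int,
    spacing: float,
    box_xy: np.ndarray,
) -> list[np.ndarray]:
    """Compact hexagonal patches with the requested total site count.

    When the requested number of patches cannot be placed without overlap
    (dense systems), the patch count is reduced until placement succeeds; a
    single patch that cannot fit at all is a geometry error.
    """
    if n_sites == 0:
        return []
    site_area = (math.sqrt(3) / 2) * spacing**2
    clearance = 1.5  # nm between patch edges, keeps patches DBSCAN-separate
    patch_count = max(1, min(patch_count, n_sites // 4 if n_sites >= 8 else 1))

    while True:
        sizes = [n_sites // patch_count] * patch_count
        for i in range(n_sites - sum(sizes)):
            sizes[i] += 1
        radii = [math.sqrt(k * site_area / math.pi) + spacing for k in sizes]
        if max(radii) >= float(min(box_xy)) / 2.0:
            raise GeometryError(
                f"condensed patch of radius {max(radii):.1f} nm cannot fit a "
                f"{box_xy[0]:.1f} x {box_xy[1]:.1f} nm box; lower f_lc or raise the area"
            )
        centers = _try_place_centers(rng, radii, clearance, box_xy)
        if centers is not None:
            break
        if patch_count == 1:
            raise GeometryError(
                f"cannot place a condensed patch of radius {radii[0]:.1f} nm in a "
                f"{box_xy[0]:.1f} x {box_xy[1]:.1f} nm box"
            )
        patch_count -= 1

    patches = []
    for c, k, r in zip(centers, sizes, radii):
        lattice = _hex_lattice(spacing, r + 2 * spacing)
        order = np.argsort(np.linalg.norm(lattice, axis=1), kind="stable")
        if lattice.shape[0] < k:
            raise GeometryError("internal: lattice smaller than requested patch")
        sites = lattice[order[:k]] + c
        # row-major ordering so consecutive sites are adjacent (chain pairing)
        row = np.round(sites[:, 1] / (spacing * math.sqrt(3) / 2)).astype(int)
        patches.append(sites[np.lexsort((sites[:, 0], row))])
    return patches


def _grid_candidates(min_dist: float, box_xy: np.ndarray) -> list[tuple[int, int, float]]:
    """Feasible stretched-hexagonal tilings of the periodic box.

    Each candidate is (columns, rows, shortest lattice neighbor distance)
    with the neighbor distance strictly above ``min_dist`` so jitter room
    remains; rows are even to keep the half-column offset periodic across
    the seam.  Sorted sparsest-first (most jitter, most disorder).
    """
    out = []
    nx_max = int(box_xy[0] / min_dist) + 1
    ny_max = int(box_xy[1] / (0.5 * min_dist)) + 2
    for nx in range(1, nx_max + 1):
        sx = box_xy[0] / nx
        if sx <= min_dist * 1.005:
            continue
        for ny in range(2, ny_max + 1, 2):
            dy = box_xy[1] / ny
            d0 = min(sx, math.hypot(sx / 2.0, dy), 2 * dy)
            if d0 > min_dist * 1.005:
                out.append((nx, ny, d0))
    out.sort(key=lambda c: (c[0] * c[1], -c[2]))
    return out


def _jittered_grid(
    rng: np.random.Generator, s: tuple[int, int, float], min_dist: float, box_xy: np.ndarray
) -> np.ndarray:
    """Jittered pseudo-hexagonal grid tiling the periodic box exactly.

    ``s`` is a candidate from :func:`_grid_candidates`.  Each site is
    jittered by up to half the slack between the lattice's shortest
    neighbor distance and ``min_dist``, which guarantees any two sites
    (seam pairs included) stay >= ``min_dist`` apart.
    """
    nx, ny, d0 = s  # chosen by _grid_candidates
    sx, dy = box_xy[0] / nx, box_xy[1] / ny
    jitter = (d0 - min_dist) / 2.0

    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    x = ii * sx + (jj % 2) * sx / 2.0
    y = jj * dy
    pts = np.column_stack([x.ravel(), y.ravel()]).astype(float)
    angles = rng.uniform(0, 2 * math.pi, len(pts))
    radii = jitter * np.sqrt(rng.uniform(0, 1, len(pts)))
    pts += np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return np.mod(pts, box_xy)


def _blue_noise_sites(
    rng: np.random.Generator,
    n_needed: int,
    min_dist: float,
    box_xy: np.ndarray,
    exclude: np.ndarray,
    exclude_radius: float,
    bead_xy: np.ndarray | None = None,
    bead_radius: float = 0.3,
) -> np.ndarray:
    """Blue-noise marker sites: >= ``min_dist`` between any two, outside the
    exclusion zones (condensed lattice sites; protein beads with their own,
    smaller radius so lipids can still reach contact range of the protein).

    A jittered hexagonal grid guarantees the minimum distance while breaking
    crystalline order; the spacing starts near the density demanded by the
    free area and shrinks until enough free sites survive, down to the
    packing limit (a geometry error).
    """
    area = float(box_xy[0] * box_xy[1])
    candidates = [c for c in _grid_candidates(min_dist, box_xy) if c[0] * c[1] >= n_needed]
    if not candidates:
        raise GeometryError(
            f"expanded-phase packing infeasible: {n_needed} markers at minimum "
            f"distance {min_dist} nm exceed the packing limit of the available "
            f"{area:.0f} nm^2"
        )
    # escalate grid density geometrically until enough sites survive exclusion
    counts = [c[0] * c[1] for c in candidates]
    target, tried = n_needed, set()
    while True:
        idx = next((i for i, c in enumerate(counts) if c >= target), None)
        if idx is None:
            break
        if idx not in tried:
            tried.add(idx)
            pts = _jittered_grid(rng, candidates[idx], min_dist, box_xy)
            free = _min_dist_to(pts, exclude, box_xy) > exclude_radius
            if bead_xy is not None and len(bead_xy):
                free &= _min_dist_to(pts, bead_xy, box_xy) > bead_radius
            pts = pts[free]
            if len(pts) >= n_needed:
                pick = rng.choice(len(pts), size=n_needed, replace=False)
                return pts[np.sort(pick)]
        target = int(target * 1.12) + 1
    raise GeometryError(
        f"expanded-phase packing infeasible: could not free {n_needed} sites at "
        f"minimum distance {min_dist} nm in {area:.0f} nm^2"
    )


# ---------------------------------------------------------------------------
# monolayer generator


def _build_leaflet(
    rng: np.random.Generator,
    spec: MonolayerSpec,
    box: np.ndarray,
    z0: float,
    sign: float,
    leaflet: str,
    with_protein: bool,
):
    """Returns (atom rows, marker truth rows, protein bead xyz or None)."""
    zm = spec.z_model
    counts = _largest_remainder(spec.composition, spec.n_lipids_per_leaflet)
    n_pl = counts.get("DPPC", 0) + counts.get("POPC", 0) + counts.get("POPG", 0)
    n_chol = counts.get("CHOL", 0)
    n_chains = 2 * n_pl + n_chol
    n_lc = round(spec.f_lc * n_chains)

    box_xy = box[:2]
    beads = None
    bead_xy = np.empty((0, 2))
    if with_protein and spec.protein is not None:
        center = 0.5 * box_xy
        beads = _protein_beads(spec.protein, center, z0, sign)
        bead_xy = beads[:, :2]

    patches = _place_patches(rng, n_lc, spec.patch_count, spec.lattice_spacing, box_xy)
    lc_sites_list = []
    for sites in patches:
        sites = np.mod(sites, box_xy)
        if beads is not None:
            d = _min_dist_to(sites, bead_xy, box_xy)
            demote = d <= 0.35  # inside the protein footprint: never a lipid site
            in_halo = (d <= spec.protein.halo_width) & ~demote
            demote |= in_halo & (rng.uniform(size=len(sites)) < spec.protein.halo_lc_suppression)
            sites = sites[~demote]
        lc_sites_list.append(sites)
    lc_sites = np.concatenate(lc_sites_list) if lc_sites_list else np.empty((0, 2))

    if n_chol == 0 and len(lc_sites) % 2:
        lc_sites = lc_sites[:-1]  # parity: sterol-free lipids come in site pairs
    n_le = n_chains - len(lc_sites)
    # expanded markers stay out of DBSCAN reach of condensed cores; near the
    # protein only steric overlap is excluded so contacts remain possible
    le_sites = _blue_noise_sites(
        rng, n_le, spec.le_min_distance, box_xy, lc_sites, exclude_radius=0.65,
        bead_xy=bead_xy if beads is not None else None,
    ) if n_le else np.empty((0, 2))
    # order rows so consecutive expanded sites pair into one lipid
    if len(le_sites):
        row = np.round(le_sites[:, 1] / (spec.le_min_distance * 0.866)).astype(int)
        le_sites = le_sites[np.lexsort((le_sites[:, 0], row))]

    # split condensed sites among phospholipids (2 chains each) and
    # cholesterol (1), roughly in proportion; the expanded split then takes
    # whatever molecules remain
    m_lc = len(lc_sites)
    n_chol_lc = min(int(round(m_lc * n_chol / max(n_chains, 1))), n_chol, m_lc)
    if (m_lc - n_chol_lc) % 2:  # parity: phospholipids need site pairs
        n_chol_lc += 1 if n_chol_lc < min(n_chol, m_lc) else -1
    n_pl_lc = (m_lc - n_chol_lc) // 2
    n_pl_le, n_chol_le = n_pl - n_pl_lc, n_chol - n_chol_lc
    if n_chol_lc < 0 or n_pl_lc > n_pl or len(le_sites) != 2 * n_pl_le + n_chol_le:
        raise GeometryError(
            "chain-site bookkeeping failed: molecule counts do not add up "
            f"({n_pl_lc}+{n_pl_le} phospholipids, {n_chol_lc}+{n_chol_le} sterols)"
        )
    pl_lc = lc_sites[: 2 * n_pl_lc].reshape(n_pl_lc, 2, 2)
    chol_lc = lc_sites[2 * n_pl_lc:]
    pl_le = le_sites[: 2 * n_pl_le].reshape(n_pl_le, 2, 2)
    chol_le = le_sites[2 * n_pl_le:]

    # fixed type order (DPPC block first): the k-th phospholipid of a leaflet
    # has the same residue name in every configuration generated from the
    # same spec shape, so compression stacks share one topology.  Condensed
    # sites are filled from the front, i.e. DPPC condenses preferentially.
    pl_types = np.array(
        ["DPPC"] * counts.get("DPPC", 0)
        + ["POPC"] * counts.get("POPC", 0)
        + ["POPG"] * counts.get("POPG", 0),
        dtype=object,
    )

    chain_end_name = {"DPPC": ("C216", "C316"), "POPC": ("C218", "C316"), "POPG": ("C218", "C316")}
    atoms = []  # (resname, atom_name, x, y, z)
    truth = []  # (atom offset within leaflet, phase)

    def norm(v: float) -> float:
        return float(rng.normal(0.0, v))

    pl_blocks = [(pl_lc, "Lc"), (pl_le, "Le")]
    pl_i = 0
    for block, phase in pl_blocks:
        for pair in block:
            resname = pl_types[pl_i]
            pl_i += 1
            (ax, ay), (bx, by) = pair
            # the two chains may straddle a periodic image; head sits between
            mid = pair[0] + 0.5 * minimum_image(pair[1] - pair[0], box_xy)
            px, py = np.mod(mid, box_xy)
            zp = z0 + norm(zm.phosphorus_sigma)
            end2, end3 = chain_end_name[resname]
            mol = [
                (resname, "P", px, py, zp),
                (resname, "C1", px, py, z0 + sign * zm.glycerol_offset),
                (resname, "C22", ax, ay, z0 + sign * zm.chain_start_offset),
                (resname, "C210", ax, ay, z0 + sign * zm.marker_offset + norm(zm.marker_sigma)),
                (resname, end2, ax, ay, z0 + sign * zm.chain_end_offset),
                (resname, "C32", bx, by, z0 + sign * zm.chain_start_offset),
                (resname, "C310", bx, by, z0 + sign * zm.marker_offset + norm(zm.marker_sigma)),
                (resname, end3, bx, by, z0 + sign * zm.chain_end_offset),
            ]
            for name_idx, entry in enumerate(mol):
                atoms.append(entry)
                if entry[1] in ("C210", "C310"):
                    truth.append((len(atoms) - 1, phase))
            atoms.append(None)  # molecule separator

    for block, phase in [(chol_lc, "Lc"), (chol_le, "Le")]:
        for (sx, sy) in block:
            mol = [
                ("CHL1", "O3", sx, sy, z0 + sign * 0.3 + norm(0.05)),
                ("CHL1", "C3", sx, sy, z0 + sign * 0.5),
                ("CHL1", "C14", sx, sy, z0 + sign * zm.marker_offset + norm(zm.marker_sigma)),
                ("CHL1", "C17", sx, sy, z0 + sign * 1.3),
            ]
            for entry in mol:
                atoms.append(entry)
                if entry[1] == "C14":
                    truth.append((len(atoms) - 1, phase))
            atoms.append(None)

    return atoms, truth, beads


def generate_monolayer(spec: MonolayerSpec) -> tuple[Topology, Frame, MonolayerTruth]:
    """Build a two-leaflet monolayer configuration with known phase labels.

    The two leaflets are mirrored about the aqueous slab in the middle of the
    box: the lower interface sits at Lz/4 with its chains pointing down, the
    upper at 3·Lz/4 pointing up.  The optional pseudo-protein is placed in
    the upper leaflet.  Roles and leaflets are already assigned on the
    returned topology.
    """
    rng = np.random.default_rng(spec.seed)
    area = spec.n_lipids_per_leaflet * spec.apl / 100.0  # nm^2
    L = math.sqrt(area)
    box = np.array([L, L, spec.box_height])

    all_rows = []  # (mol_id, resname, atom_name, x, y, z)
    truth_rows = []
    protein_xy: dict[str, np.ndarray] = {}
    mol_id = 0

    for leaflet, z_frac, sign in (("lower", 0.25, -1.0), ("upper", 0.75, 1.0)):
        z0 = z_frac * spec.box_height
        with_protein = leaflet == "upper" and spec.protein is not None
        atoms, truth, beads = _build_leaflet(rng, spec, box, z0, sign, leaflet, with_protein)

        offset_to_global: dict[int, int] = {}
        mol_id += 1
        for local_idx, entry in enumerate(atoms):
            if entry is None:
                mol_id += 1
                continue
            resname, name, x, y, z = entry
            offset_to_global[local_idx] = len(all_rows)
            all_rows.append((mol_id, resname, name, x % box[0], y % box[1], z))
        mol_id -= 1  # trailing separator

        for local_idx, phase in truth:
            gi = offset_to_global[local_idx]
            truth_rows.append(
                {
                    "leaflet": leaflet,
                    "mol_id": all_rows[gi][0],
                    "atom_name": all_rows[gi][2],
                    "x": all_rows[gi][3],
                    "y": all_rows[gi][4],
                    "phase": phase,
                }
            )

        if beads is not None:
            protein_xy[leaflet] = beads[:, :2].copy()
            for b, bead in enumerate(beads):
                mol_id += 1
                resname = spec.protein.residue_names[b % len(spec.protein.residue_names)]
                all_rows.append((mol_id, resname, "CA", bead[0] % box[0], bead[1] % box[1], bead[2]))

    n = len(all_rows)
    topology = Topology(
        atom_id=np.arange(1, n + 1),
        mol_id=np.array([r[0] for r in all_rows]),
        resname=np.array([r[1] for r in all_rows], dtype=object),
        atom_name=np.array([r[2] for r in all_rows], dtype=object),
    )
    positions = np.array([[r[3], r[4], r[5]] for r in all_rows])
    frame = Frame(time=0.0, box=box, positions=positions)
    topology = assign_roles(topology)
    topology = assign_leaflets(frame, topology)

    truth = MonolayerTruth(
        markers=pd.DataFrame(truth_rows),
        f_lc_target=spec.f_lc,
        protein_xy=protein_xy,
    )
    return topology, frame, truth


# ---------------------------------------------------------------------------
# Brownian tracks


def generate_brownian(spec: BrownianSpec) -> tuple[Topology, Trajectory, np.ndarray]:
    """Free 2D Brownian motion of tracer particles with known D.

    Steps are independent Gaussians with per-axis variance 2·D·dt; the
    trajectory is wrapped into the box and the unwrapped coordinates are
    returned as ground truth (same shape as ``trajectory.positions``).
    Tracers are single-atom phosphorus-tagged molecules in a single leaflet.
    """
    rng = np.random.default_rng(spec.seed)
    n, steps = spec.n_particles, spec.n_steps
    box = np.array([spec.box_xy, spec.box_xy, 10.0])

    start = rng.uniform(0, spec.box_xy, size=(n, 2))
    sigma = math.sqrt(2.0 * spec.D_true * spec.dt)
    increments = rng.normal(0.0, sigma, size=(steps, n, 2)) if sigma > 0 else np.zeros((steps, n, 2))
    xy = np.concatenate([start[None], start[None] + np.cumsum(increments, axis=0)], axis=0)

    unwrapped = np.zeros((steps + 1, n, 3))
    unwrapped[:, :, :2] = xy
    unwrapped[:, :, 2] = 5.0
    wrapped = unwrapped.copy()
    wrapped[:, :, :2] = np.mod(xy, spec.box_xy)

    topology = Topology(
        atom_id=np.arange(1, n + 1),
        mol_id=np.arange(1, n + 1),
        resname=np.array(["DPPC"] * n, dtype=object),
        atom_name=np.array(["P"] * n, dtype=object),
    )
    topology = assign_roles(topology, TRACER_ROLE_CONFIG)
    topology.leaflet = np.array(["upper"] * n, dtype=object)

    trajectory = Trajectory(
        times=np.arange(steps + 1) * spec.dt,
        boxes=np.tile(box, (steps + 1, 1)),
        positions=wrapped,
    )
    return topology, trajectory, unwrapped


# ---------------------------------------------------------------------------
# pressure series


def generate_pressure_series(
    times: np.ndarray,
    gamma_schedule,
    gamma0: float = 70.0,
    Lz: float = 15.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    apl_range: tuple[float, float] = (90.0, 45.0),
) -> tuple[PressureSeries, pd.DataFrame]:
    """Plant an exact surface-tension schedule in pressure-tensor columns.

    ``gamma_schedule`` maps time (ns) to the target tension (mN/m); it may
    be a callable or a constant.  Before noise, the two-interface tension
    formula recovers the schedule exactly:  Pzz is held at 1 bar and the
    lateral components absorb the anisotropy.  Gaussian noise of sd
    ``noise_sd`` (bar) is then added to Pxx and Pyy independently.  The APL
    column follows a compression ramp linear in the box edge between the
    given APL endpoints.

    Returns the series and a truth table (time, gamma_true, pi_true, APL).
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    if callable(gamma_schedule):
        gamma_true = np.array([float(gamma_schedule(t)) for t in times])
    else:
        gamma_true = np.full(times.shape, float(gamma_schedule))

    pzz = np.ones_like(times)
    # gamma = 0.1*(Lz/2)*(Pzz - (Pxx+Pyy)/2)  =>  lateral mean below Pzz
    lateral = pzz - gamma_true / (0.1 * Lz / 2.0)
    pxx = lateral + rng.normal(0.0, noise_sd, times.shape)
    pyy = lateral + rng.normal(0.0, noise_sd, times.shape)

    edge = np.sqrt(np.linspace(apl_range[0], apl_range[1], times.size))
    apl = edge**2

    series = PressureSeries(
        time=times, Pxx=pxx, Pyy=pyy, Pzz=pzz, Lz=np.full(times.shape, Lz), apl=apl
    )
    truth = pd.DataFrame(
        {"time": times, "gamma_true": gamma_true, "pi_true": gamma0 - gamma_true, "APL": apl}
    )
    return series, truth


# ---------------------------------------------------------------------------
# compression stack


def generate_compression_stack(
    spec: MonolayerSpec,
    apl_grid,
    f_lc_of_apl,
    frame_spacing: float = 100.0,
) -> list[tuple[Topology, Frame, MonolayerTruth]]:
    """One monolayer configuration per APL with a planted f_lc(APL).

    ``f_lc_of_apl`` is a callable (or mapping) that must be monotone
    nonincreasing in APL — compression condenses, expansion melts.  Frames
    are stamped ``frame_spacing`` ns apart in grid order.
    """
    apl_grid = list(apl_grid)
    if callable(f_lc_of_apl):
        f_values = [float(f_lc_of_apl(a)) for a in apl_grid]
    else:
        f_values = [float(f_lc_of_apl[a]) for a in apl_grid]

    order = np.argsort(apl_grid)
    ordered_f = [f_values[i] for i in order]
    if any(b > a + 1e-12 for a, b in zip(ordered_f, ordered_f[1:])):
        raise ValueError("f_lc_of_apl must be monotone nonincreasing in APL")

    out = []
    for i, (apl, f) in enumerate(zip(apl_grid, f_values)):
        sub = replace(spec, apl=float(apl), f_lc=f, seed=spec.seed + 1000 * i)
        topology, frame, truth = generate_monolayer(sub)
        frame.time = i * frame_spacing
        out.append((topology, frame, truth))
    return out
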