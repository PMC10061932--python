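"""Core containers: topology with analysis roles, frames, trajectories,
pressure-tensor time series.

A monolayer system is described by a flat atom table (one molecule per GRO
residue) plus per-atom *role* tags that drive every downstream analysis:

``phosphorus``
    the PO4 phosphorus of each phospholipid; the alignment reference for
    transverse density profiles and the default lateral-diffusion tracker.
``chain_marker``
    the 10th acyl-chain carbon of each phospholipid chain (two per lipid),
    the per-chain point used for condensed-phase clustering.
``chol_marker``
    the C14 ring carbon of cholesterol, which sits at the same depth as the
    chain markers and is clustered together with them.
``protein``
    every heavy atom of the (optional) surfactant protein.

Roles are assigned from a residue-name keyed configuration; the defaults
target CHARMM36 atom nomenclature and are fully overridable (TOML or dict).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "PressureSeries",
    "RoleConfig",
    "DEFAULT_ROLE_CONFIG",
    "load_role_config",
    "assign_roles",
    "assign_leaflets",
    "default_is_heavy",
    "atom_masses",
]

LIPID_TYPES = ("DPPC", "POPC", "POPG", "CHOL")

#: atomic masses (amu) keyed by element symbol, for mass-weighted densities
_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}


def default_is_heavy(atom_name: str) -> bool:
    """Heavy-atom rule: first alphabetic character of the name is not H."""
    stripped = atom_name.lstrip("0123456789")
    return bool(stripped) and stripped[0].upper() != "H"


def _element_of(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    return stripped[0].upper() if stripped else "C"


def atom_masses(atom_names: np.ndarray) -> np.ndarray:
    """Per-atom masses (amu) inferred from the leading element letter."""
    return np.array([_ELEMENT_MASS.get(_element_of(n), 12.011) for n in atom_names])


@dataclass
class Topology:
    """Atom table plus role tags and per-molecule annotations.

    Attributes
    ----------
    atom_id, mol_id : int arrays, one entry per atom
    resname, atom_name : str arrays, one entry per atom
    is_heavy : bool array
    roles : dict of bool arrays keyed by role name; populated by
        :func:`assign_roles` (``phosphorus``, ``chain_marker``, ``chol_marker``,
        ``protein``, ``lipid``)
    mol_type : str array indexed like ``mol_ids()`` output
        (``DPPC``/``POPC``/``POPG``/``CHOL``/``PROTEIN``)
    leaflet : str array per molecule (``upper``/``lower``), filled by
        :func:`assign_leaflets`
    """

    atom_id: np.ndarray
    mol_id: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    is_heavy: np.ndarray = None  # type: ignore[assignment]
    roles: dict = field(default_factory=dict)
    mol_type: np.ndarray | None = None
    leaflet: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atom_id = np.asarray(self.atom_id, dtype=np.intp)
        self.mol_id = np.asarray(self.mol_id, dtype=np.intp)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        if self.is_heavy is None:
            self.is_heavy = np.array([default_is_heavy(n) for n in self.atom_name])
        self.is_heavy = np.asarray(self.is_heavy, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return self.atom_id.size

    def mol_ids(self) -> np.ndarray:
        """Unique molecule ids in first-appearance order."""
        _, idx = np.unique(self.mol_id, return_index=True)
        return self.mol_id[np.sort(idx)]

    @property
    def n_molecules(self) -> int:
        return np.unique(self.mol_id).size

    def mol_index(self) -> np.ndarray:
        """Per-atom index into ``mol_ids()`` order."""
        mids = self.mol_ids()
        lookup = {m: i for i, m in enumerate(mids)}
        return np.array([lookup[m] for m in self.mol_id], dtype=np.intp)

    def role_mask(self, role: str) -> np.ndarray:
        if role not in self.roles:
            raise KeyError(
                f"role {role!r} not assigned; call assign_roles() first "
                f"(available: {sorted(self.roles)})"
            )
        return self.roles[role]

    def atom_leaflet(self) -> np.ndarray:
        """Per-atom leaflet labels (requires assign_leaflets)."""
        if self.leaflet is None:
            raise ValueError("leaflets not assigned; call assign_leaflets() first")
        return self.leaflet[self.mol_index()]

    def atom_lipid_type(self) -> np.ndarray:
        if self.mol_type is None:
            raise ValueError("lipid types not assigned; call assign_roles() first")
        return self.mol_type[self.mol_index()]

    def masses(self) -> np.ndarray:
        return atom_masses(self.atom_name)

    def to_frame_table(self) -> pd.DataFrame:
        """Tidy per-atom view (for debugging / TSV export)."""
        data = {
            "atom_id": self.atom_id,
            "mol_id": self.mol_id,
            "resname": self.resname,
            "atom_name": self.atom_name,
            "is_heavy": self.is_heavy,
        }
        for role, mask in self.roles.items():
            data[f"role_{role}"] = mask
        if self.mol_type is not None:
            data["lipid_type"] = self.atom_lipid_type()
        if self.leaflet is not None:
            data["leaflet"] = self.atom_leaflet()
        return pd.DataFrame(data)


@dataclass
class Frame:
    """One configuration: time (ns), orthorhombic box (nm), positions (nm)."""

    time: float
    box: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.box.shape != (3,):
            raise ValueError(f"box must have shape (3,), got {self.box.shape}")
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be positive, got {tuple(self.box)}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Stack of frames on a shared atom set."""

    times: np.ndarray
    boxes: np.ndarray
    positions: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if not (len(self.times) == len(self.boxes) == len(self.positions)):
            raise ValueError("times, boxes and positions must have equal length")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), box=self.boxes[i], positions=self.positions[i])

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def from_frames(cls, frames: list[Frame]) -> "Trajectory":
        if not frames:
            raise ValueError("cannot build a trajectory from zero frames")
        return cls(
            times=np.array([f.time for f in frames]),
            boxes=np.stack([f.box for f in frames]),
            positions=np.stack([f.positions for f in frames]),
        )


@dataclass
class PressureSeries:
    """Pressure-tensor diagonal and box height vs time.

    Units: time ns, pressures bar, ``Lz`` nm, optional area per lipid Å².
    """

    time: np.ndarray
    Pxx: np.ndarray
    Pyy: np.ndarray
    Pzz: np.ndarray
    Lz: np.ndarray
    apl: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = [self.time, self.Pxx, self.Pyy, self.Pzz, self.Lz]
        arrays = [np.asarray(a, dtype=float) for a in arrays]
        self.time, self.Pxx, self.Pyy, self.Pzz, self.Lz = arrays
        if self.apl is not None:
            self.apl = np.asarray(self.apl, dtype=float)
            arrays.append(self.apl)
        n = self.time.size
        if any(a.size != n for a in arrays):
            raise ValueError("all pressure-series columns must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("pressure-series time must be strictly increasing")

    def to_table(self) -> pd.DataFrame:
        data = {
            "time": self.time,
            "Pxx": self.Pxx,
            "Pyy": self.Pyy,
            "Pzz": self.Pzz,
            "Lz": self.Lz,
        }
        if self.apl is not None:
            data["APL"] = self.apl
        return pd.DataFrame(data)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PressureSeries":
        apl = table["APL"].to_numpy() if "APL" in table.columns else None
        return cls(
            time=table["time"].to_numpy(),
            Pxx=table["Pxx"].to_numpy(),
            Pyy=table["Pyy"].to_numpy(),
            Pzz=table["Pzz"].to_numpy(),
            Lz=table["Lz"].to_numpy(),
            apl=apl,
        )


# ---------------------------------------------------------------------------
# role assignment


@dataclass(frozen=True)
class ResidueRoles:
    """Role map for one residue name."""

    lipid_type: str
    phosphorus: str | None = None
    chain_markers: tuple[str, ...] = ()
    chain_starts: tuple[str, ...] = ()
    chain_ends: tuple[str, ...] = ()
    reference_atom: str | None = None  # lateral-diffusion tracking atom


RoleConfig = Mapping[str, ResidueRoles]

# CHARMM36 nomenclature: phosphate P; 10th chain carbons C210 (sn-2) and
# C310 (sn-1); cholesterol residue CHL1 with ring carbon C14 and hydroxyl O3.
DEFAULT_ROLE_CONFIG: dict[str, ResidueRoles] = {
    "DPPC": ResidueRoles("DPPC", "P", ("C210", "C310"), ("C22", "C32"), ("C216", "C316"), "P"),
    "POPC": ResidueRoles("POPC", "P", ("C210", "C310"), ("C22", "C32"), ("C218", "C316"), "P"),
    "POPG": ResidueRoles("POPG", "P", ("C210", "C310"), ("C22", "C32"), ("C218", "C316"), "P"),
    "CHL1": ResidueRoles("CHOL", None, ("C14",), (), (), "O3"),
}

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD", "HSE",
    "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def load_role_config(path: str | Path) -> dict[str, ResidueRoles]:
    """Load a residue→roles map from TOML.

    Each table is keyed by residue name::

        [DPPC]
        lipid_type = "DPPC"
        phosphorus = "P"
        chain_markers = ["C210", "C310"]
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    config: dict[str, ResidueRoles] = {}
    for resname, entry in raw.items():
        config[resname] = ResidueRoles(
            lipid_type=entry["lipid_type"],
            phosphorus=entry.get("phosphorus"),
            chain_markers=tuple(entry.get("chain_markers", ())),
            chain_starts=tuple(entry.get("chain_starts", ())),
            chain_ends=tuple(entry.get("chain_ends", ())),
            reference_atom=entry.get("reference_atom"),
        )
    return config


def assign_roles(
    topology: Topology,
    role_config: RoleConfig | None = None,
    protein_resnames: set[str] | None = None,
) -> Topology:
    """Tag atoms with analysis roles based on residue and atom names.

    Raises
    ------
    ValueError
        if a residue name is neither in the config nor a protein residue, or
        if a phospholipid does not contain exactly one phosphorus atom or
        exactly two chain-marker atoms (one per acyl chain).
    """
    config = dict(DEFAULT_ROLE_CONFIG if role_config is None else role_config)
    protein_set = _PROTEIN_RESNAMES if protein_resnames is None else protein_resnames

    n = topology.n_atoms
    roles = {
        "phosphorus": np.zeros(n, dtype=bool),
        "chain_marker": np.zeros(n, dtype=bool),
        "chol_marker": np.zeros(n, dtype=bool),
        "protein": np.zeros(n, dtype=bool),
        "lipid": np.zeros(n, dtype=bool),
    }

    mids = topology.mol_ids()
    mol_type = np.empty(mids.size, dtype=object)
    unknown: set[str] = set()

    for i, mid in enumerate(mids):
        sel = topology.mol_id == mid
        resnames = set(topology.resname[sel])
        if resnames & protein_set:
            mol_type[i] = "PROTEIN"
            roles["protein"][sel & topology.is_heavy] = True
            continue
        # lipids are single-residue molecules
        resname = topology.resname[sel][0]
        if resname not in config:
            unknown.add(resname)
            continue
        entry = config[resname]
        mol_type[i] = entry.lipid_type
        heavy_sel = sel & topology.is_heavy
        roles["lipid"][heavy_sel] = True
        names = topology.atom_name
        if entry.phosphorus is not None:
            p_mask = heavy_sel & (names == entry.phosphorus)
            if p_mask.sum() != 1:
                raise ValueError(
                    f"phospholipid molecule {mid} ({resname}) matched "
                    f"{int(p_mask.sum())} phosphorus atoms named {entry.phosphorus!r}; "
                    "exactly one is required"
                )
            roles["phosphorus"] |= p_mask
            if entry.chain_markers:  # marker-less entries: headgroup-only tracers
                marker_mask = heavy_sel & np.isin(names, entry.chain_markers)
                if marker_mask.sum() != 2:
                    raise ValueError(
                        f"phospholipid molecule {mid} ({resname}) matched "
                        f"{int(marker_mask.sum())} chain markers {entry.chain_markers}; "
                        "exactly two are required (sn-1 and sn-2)"
                    )
                roles["chain_marker"] |= marker_mask
        else:
            marker_mask = heavy_sel & np.isin(names, entry.chain_markers)
            if marker_mask.sum() != 1:
                raise ValueError(
                    f"sterol molecule {mid} ({resname}) matched "
                    f"{int(marker_mask.sum())} marker atoms {entry.chain_markers}; "
                    "exactly one is required"
                )
            roles["chol_marker"] |= marker_mask

    if unknown:
        raise ValueError(
            "residue names without role mapping and not recognized as protein: "
            + ", ".join(sorted(unknown))
        )

    return replace(topology, roles=roles, mol_type=mol_type)


def _split_two_means(z: np.ndarray) -> tuple[float, float, float]:
    """Exact 1D two-means: scan all sorted splits minimizing within-class SSE.

    Returns (lower mean, upper mean, midpoint).
    """
    zs = np.sort(z)
    n = zs.size
    csum = np.cumsum(zs)
    csq = np.cumsum(zs**2)
    best, best_k = np.inf, 1
    for k in range(1, n):
        m1 = csum[k - 1] / k
        m2 = (csum[-1] - csum[k - 1]) / (n - k)
        sse = (csq[k - 1] - k * m1**2) + (csq[-1] - csq[k - 1] - (n - k) * m2**2)
        if sse < best:
            best, best_k = sse, k
    m1 = csum[best_k - 1] / best_k
    m2 = (csum[-1] - csum[best_k - 1]) / (n - best_k)
    return m1, m2, 0.5 * (m1 + m2)


def assign_leaflets(
    frame: Frame,
    topology: Topology,
    min_separation: float = 1.0,
    single_leaflet: bool = False,
) -> Topology:
    """Partition molecules into upper/lower leaflets by phosphorus depth.

    Phospholipids are split at the midpoint between the two phosphorus
    z-population means (exact 1D two-means).  Molecules without a phosphorus
    (cholesterol, protein) go to the leaflet whose phosphorus population mean
    is nearest to their heavy-atom mean z.

    Parameters
    ----------
    min_separation:
        Minimum distance (nm) between the two phosphorus population means for
        the configuration to count as two leaflets.  Below it a configuration
        error is raised unless ``single_leaflet`` is set, in which case every
        molecule is labeled ``upper``.
    """
    p_mask = topology.role_mask("phosphorus")
    if not p_mask.any():
        raise ValueError("no phosphorus atoms tagged; assign_roles() first")
    z = frame.positions[:, 2]

    mids = topology.mol_ids()
    mol_index = topology.mol_index()
    leaflet = np.empty(mids.size, dtype=object)

    if single_leaflet:
        leaflet[:] = "upper"
        return replace(topology, leaflet=leaflet)

    pz = z[p_mask]
    if pz.size < 2:
        raise ValueError("need at least 2 phosphorus atoms for two-leaflet assignment")
    m_lo, m_hi, mid_z = _split_two_means(pz)
    if abs(m_hi - m_lo) < min_separation:
        raise ValueError(
            f"phosphorus z distribution looks unimodal (population means "
            f"{m_lo:.3f} and {m_hi:.3f} nm, separation < {min_separation} nm); "
            "pass single_leaflet=True for a one-leaflet system"
        )

    # molecules carrying a phosphorus: classify by that atom's z
    p_mol = mol_index[p_mask]
    p_upper = z[p_mask] > mid_z
    has_p = np.zeros(mids.size, dtype=bool)
    for mi, up in zip(p_mol, p_upper):
        has_p[mi] = True
        leaflet[mi] = "upper" if up else "lower"

    # the rest: nearest phosphorus population by heavy-atom mean z
    heavy_z_sum = np.zeros(mids.size)
    heavy_z_cnt = np.zeros(mids.size)
    np.add.at(heavy_z_sum, mol_index[topology.is_heavy], z[topology.is_heavy])
    np.add.at(heavy_z_cnt, mol_index[topology.is_heavy], 1)
    for mi in np.flatnonzero(~has_p):
        mz = heavy_z_sum[mi] / max(heavy_z_cnt[mi], 1)
        leaflet[mi] = "upper" if abs(mz - m_hi) <= abs(mz - m_lo) else "lower"

    return replace(topology, leaflet=leaflet)
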