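"""Reader/writer for the GROMACS GRO coordinate format (fixed column, nm).

Single frames and concatenated multi-frame files are supported; multi-frame
GRO is the reference text trajectory format for this package.  Velocities
are ignored on read and never written.  Only orthorhombic boxes (three box
numbers, or nine with zero off-diagonal components) are accepted.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import TextIO

import numpy as np

from .topology import Frame, Topology, Trajectory

__all__ = ["read_gro", "read_gro_frames", "write_gro", "write_gro_frames"]

_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


class GroParseError(ValueError):
    pass


def _parse_box(line: str, lineno: int) -> np.ndarray:
    try:
        vals = [float(x) for x in line.split()]
    except ValueError:
        raise GroParseError(f"line {lineno}: malformed box line {line.strip()!r}") from None
    if len(vals) == 3:
        box = np.array(vals)
    elif len(vals) == 9:
        if any(abs(v) > 1e-9 for v in vals[3:]):
            raise GroParseError(
                f"line {lineno}: non-orthorhombic box (off-diagonal components "
                "present); only rectangular cells are supported"
            )
        box = np.array(vals[:3])
    else:
        raise GroParseError(f"line {lineno}: box line must have 3 or 9 numbers")
    if np.any(box <= 0):
        raise GroParseError(f"line {lineno}: box edges must be positive, got {vals[:3]}")
    return box


def _read_block(fh: TextIO, lineno: int) -> tuple[Topology, Frame, int] | None:
    title = fh.readline()
    if title == "":
        return None
    lineno += 1
    count_line = fh.readline()
    lineno += 1
    try:
        n_atoms = int(count_line.strip())
    except ValueError:
        raise GroParseError(
            f"line {lineno}: malformed atom-count line {count_line.strip()!r}"
        ) from None
    if n_atoms < 1:
        raise GroParseError(f"line {lineno}: atom count must be >= 1, got {n_atoms}")

    mol_id = np.empty(n_atoms, dtype=np.intp)
    resname = np.empty(n_atoms, dtype=object)
    atom_name = np.empty(n_atoms, dtype=object)
    atom_id = np.empty(n_atoms, dtype=np.intp)
    positions = np.empty((n_atoms, 3))

    for i in range(n_atoms):
        line = fh.readline()
        lineno += 1
        if line == "":
            raise GroParseError(
                f"line {lineno}: file ended after {i} atom lines but the header "
                f"declared {n_atoms} atoms"
            )
        # fixed columns: resid(5) resname(5) name(5) atomid(5) x(8) y(8) z(8)
        try:
            mol_id[i] = int(line[0:5])
            resname[i] = line[5:10].strip()
            atom_name[i] = line[10:15].strip()
            atom_id[i] = int(line[15:20])
            positions[i, 0] = float(line[20:28])
            positions[i, 1] = float(line[28:36])
            positions[i, 2] = float(line[36:44])
        except (ValueError, IndexError):
            raise GroParseError(f"line {lineno}: malformed atom line {line.rstrip()!r}") from None

    box_line = fh.readline()
    lineno += 1
    if box_line.strip() == "":
        raise GroParseError(f"line {lineno}: missing box line (header atom count too large?)")
    box = _parse_box(box_line, lineno)

    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else 0.0
    topology = Topology(atom_id=atom_id, mol_id=mol_id, resname=resname, atom_name=atom_name)
    return topology, Frame(time=time, box=box, positions=positions), lineno


def read_gro(path: str | Path) -> tuple[Topology, Frame]:
    """Read the first (or only) frame of a GRO file."""
    with open(path) as fh:
        block = _read_block(fh, 0)
    if block is None:
        raise GroParseError(f"{path}: empty file")
    topology, frame, _ = block
    return topology, frame


def read_gro_frames(path: str | Path) -> tuple[Topology, Trajectory]:
    """Read a multi-frame GRO file (concatenated blocks, shared topology)."""
    frames: list[Frame] = []
    topology: Topology | None = None
    with open(path) as fh:
        lineno = 0
        while True:
            block = _read_block(fh, lineno)
            if block is None:
                break
            top_i, frame, lineno = block
            if topology is None:
                topology = top_i
            elif top_i.n_atoms != topology.n_atoms:
                raise GroParseError(
                    f"{path}: frame {len(frames)} has {top_i.n_atoms} atoms, "
                    f"expected {topology.n_atoms}"
                )
            frames.append(frame)
    if topology is None:
        raise GroParseError(f"{path}: empty file")
    return topology, Trajectory.from_frames(frames)


def _write_block(fh: TextIO, topology: Topology, frame: Frame, title: str) -> None:
    if frame.n_atoms != topology.n_atoms:
        raise ValueError(
            f"frame has {frame.n_atoms} positions but topology has {topology.n_atoms} atoms"
        )
    fh.write(f"{title} t= {frame.time:.5f}\n")
    fh.write(f"{topology.n_atoms:5d}\n")
    for i in range(topology.n_atoms):
        x, y, z = frame.positions[i]
        fh.write(
            f"{int(topology.mol_id[i]) % 100000:5d}"
            f"{str(topology.resname[i]):<5.5s}"
            f"{str(topology.atom_name[i]):>5.5s}"
            f"{int(topology.atom_id[i]) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )
    fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


def write_gro(path: str | Path, topology: Topology, frame: Frame, title: str = "monofilm") -> None:
    with open(path, "w") as fh:
        _write_block(fh, topology, frame, title)


def write_gro_frames(
    path: str | Path, topology: Topology, trajectory: Trajectory, title: str = "monofilm"
) -> None:
    with open(path, "w") as fh:
        for frame in trajectory:
            _write_block(fh, topology, frame, title)
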