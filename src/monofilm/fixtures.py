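"""Write synthetic fixture sets to disk: a multi-frame GRO compression
trajectory, a matching XVG pressure series, and ground-truth tables.

The fixture spec is TOML::

    seed = 7
    [monolayer]
    n_lipids_per_leaflet = 169
    [monolayer.protein]
    radius = 1.2
    halo_width = 1.5
    [stack]
    apl_grid = [90.0, 65.0, 55.0]
    f_lc = [0.0, 0.3, 0.7]
    frame_spacing = 100.0
    [pressure]
    gamma0 = 70.0
    noise_sd = 5.0
    dt = 0.5
    pi_start = 0.0
    pi_end = 50.0

Everything written is loadable by the run pipeline without edits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gro import write_gro_frames
from .synth import (
    MonolayerSpec,
    ProteinSpec,
    generate_compression_stack,
    generate_pressure_series,
)
from .topology import Trajectory
from .xvg import write_xvg

__all__ = ["load_fixture_spec", "write_fixture_set"]

_DEFAULT_SPEC = {
    "seed": 0,
    "monolayer": {"n_lipids_per_leaflet": 169},
    "stack": {"apl_grid": [90.0, 65.0, 55.0], "f_lc": [0.0, 0.3, 0.7], "frame_spacing": 100.0},
    "pressure": {"gamma0": 70.0, "noise_sd": 5.0, "dt": 0.5, "pi_start": 0.0, "pi_end": 50.0},
}


def load_fixture_spec(path: str | Path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    spec = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _DEFAULT_SPEC.items()}
    for key, value in raw.items():
        if isinstance(value, dict) and key in spec:
            spec[key].update(value)
        else:
            spec[key] = value
    return spec


def write_fixture_set(spec: dict | str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write one fixture set; returns the paths written."""
    if not isinstance(spec, dict):
        spec = load_fixture_spec(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(spec.get("seed", 0))

    mono_kwargs = dict(spec.get("monolayer", {}))
    protein_kwargs = mono_kwargs.pop("protein", None)
    protein = ProteinSpec(**protein_kwargs) if protein_kwargs is not None else None
    mono = MonolayerSpec(protein=protein, seed=seed, **mono_kwargs)

    stack_cfg = spec.get("stack", _DEFAULT_SPEC["stack"])
    apl_grid = [float(a) for a in stack_cfg["apl_grid"]]
    f_lc = [float(f) for f in stack_cfg["f_lc"]]
    if len(apl_grid) != len(f_lc):
        raise ValueError("stack.apl_grid and stack.f_lc must have equal length")
    spacing = float(stack_cfg.get("frame_spacing", 100.0))
    stack = generate_compression_stack(
        mono, apl_grid, dict(zip(apl_grid, f_lc)), frame_spacing=spacing
    )

    topology = stack[0][0]
    for i, (top_i, _, _) in enumerate(stack[1:], start=1):
        if not np.array_equal(top_i.resname, topology.resname):
            raise RuntimeError(f"stack frame {i} does not share the base topology")
    trajectory = Trajectory.from_frames([frame for _, frame, _ in stack])
    paths: dict[str, Path] = {}

    paths["trajectory"] = out / "trajectory.gro"
    write_gro_frames(paths["trajectory"], topology, trajectory)

    press = spec.get("pressure", _DEFAULT_SPEC["pressure"])
    gamma0 = float(press.get("gamma0", 70.0))
    t_end = len(stack) * spacing
    times = np.arange(0.0, t_end, float(press.get("dt", 0.5)))
    pi_start, pi_end = float(press.get("pi_start", 0.0)), float(press.get("pi_end", 50.0))

    def gamma_schedule(t: float) -> float:
        return gamma0 - (pi_start + (pi_end - pi_start) * t / t_end)

    series, pressure_truth = generate_pressure_series(
        times,
        gamma_schedule,
        gamma0=gamma0,
        noise_sd=float(press.get("noise_sd", 5.0)),
        seed=seed + 7919,
        apl_range=(apl_grid[0], apl_grid[-1]),
    )
    paths["pressure"] = out / "pressure.xvg"
    write_xvg(paths["pressure"], series.to_table(), title="synthetic pressure series")

    marker_rows = []
    summary_rows = []
    for f, (_, frame, truth) in enumerate(stack):
        markers = truth.markers.copy()
        markers.insert(0, "frame", f)
        markers.insert(1, "time", frame.time)
        marker_rows.append(markers)
        summary_rows.append(
            {
                "frame": f,
                "time": frame.time,
                "apl": apl_grid[f],
                "f_lc_target": f_lc[f],
                "f_lc_realized": truth.lc_fraction(),
            }
        )
    paths["truth_markers"] = out / "truth_markers.tsv"
    pd.concat(marker_rows, ignore_index=True).to_csv(
        paths["truth_markers"], sep="\t", index=False, float_format="%.8g"
    )
    paths["truth_summary"] = out / "truth_summary.tsv"
    pd.DataFrame(summary_rows).to_csv(
        paths["truth_summary"], sep="\t", index=False, float_format="%.8g"
    )
    paths["pressure_truth"] = out / "truth_pressure.tsv"
    pressure_truth.to_csv(paths["pressure_truth"], sep="\t", index=False, float_format="%.8g")
    return paths
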