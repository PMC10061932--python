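"""End-to-end orchestration: trajectory + pressure series in, tidy tables out.

The pipeline stratifies every stage by surface-pressure regime using a
single source of truth: each frame inherits the window-mean surface
pressure of the isotherm window containing it, and that value is binned
into the configured regimes.  Outputs are tab-separated tidy tables plus a
``report.json`` carrying the parameters, a config hash, library versions
and per-stage record counts, so a run is reproducible bit-for-bit from the
same inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contacts import count_contacts, normalize_contacts, stratify_by_regime
from .density import density_profile, monolayer_thickness
from .diffusion import fit_diffusion, lateral_displacements
from .gro import read_gro_frames
from .isotherm import (
    DEFAULT_REGIMES,
    PressureRegime,
    isotherm_from_series,
    regime_of,
)
from .phases import lc_fraction_vs_distance, phase_labels
from .superpose import rmsd
from .topology import PressureSeries, Topology, Trajectory, assign_leaflets, assign_roles, load_role_config
from .xvg import read_xvg

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    trajectory: str = ""
    pressure_series: str = ""
    role_map: str | None = None
    out_dir: str = "monofilm_out"
    gamma0: float = 70.0
    n_interfaces: int = 2
    window: float = 100.0  # ns
    eps: float = 0.55  # nm
    min_pts: int = 4
    min_cluster_size: int = 10
    contact_cutoff: float = 0.3  # nm
    diffusion_lag: float = 10.0  # ns
    drift_correction: bool = True
    distance_bins: list = field(default_factory=lambda: list(np.arange(0.0, 5.01, 0.5)))
    z_bins: list = field(default_factory=lambda: list(np.arange(-5.0, 3.001, 0.1)))
    regimes: list = field(default_factory=lambda: [
        [r.label, r.lower, r.upper] for r in DEFAULT_REGIMES
    ])
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window", "eps", "contact_cutoff", "diffusion_lag", "gamma0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.min_pts < 1 or self.min_cluster_size < 1:
            raise ValueError("min_pts and min_cluster_size must be >= 1")

    def regime_objects(self) -> tuple[PressureRegime, ...]:
        return tuple(PressureRegime(label, float(lo), float(hi)) for label, lo, hi in self.regimes)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        ).hexdigest()[:16]


def _write_tsv(path: Path, table: pd.DataFrame) -> int:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return len(table)


def _frame_regimes(
    trajectory: Trajectory, iso: pd.DataFrame, window: float, regimes
) -> tuple[np.ndarray, np.ndarray]:
    """Window-mean Pi and regime label for every frame."""
    t0 = iso["window_center_time"].iloc[0] - 0.5 * window
    idx = np.clip(((trajectory.times - t0) // window).astype(int), 0, len(iso) - 1)
    pi = iso["pi_mean"].to_numpy()[idx]
    return pi, regime_of(pi, regimes)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle to ``config.out_dir``.

    Returns the report dictionary.  On a stage failure all partial outputs
    are removed and a :class:`PipelineError` naming the stage is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {
        "monofilm_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "versions": _library_versions(),
        "records": {},
        "skipped": {},
    }

    def emit(name: str, table: pd.DataFrame) -> None:
        path = out / name
        report["records"][name] = _write_tsv(path, table)
        written.append(path)

    stage = "load"
    try:
        topology, trajectory = read_gro_frames(config.trajectory)
        role_config = load_role_config(config.role_map) if config.role_map else None
        topology = assign_roles(topology, role_config)
        topology = assign_leaflets(trajectory[0], topology)
        series = PressureSeries.from_table(read_xvg(config.pressure_series))
        regimes = config.regime_objects()

        stage = "isotherm"
        iso = isotherm_from_series(series, config.gamma0, config.n_interfaces, config.window)
        emit("isotherm.tsv", iso)
        frame_pi, frame_regime = _frame_regimes(trajectory, iso, config.window, regimes)

        stage = "phases"
        has_protein = bool(topology.role_mask("protein").any())
        protein_leaflets = (
            set(topology.atom_leaflet()[topology.role_mask("protein")]) if has_protein else set()
        )
        phase_rows, profile_pool = [], []
        for f, frame in enumerate(trajectory):
            for leaflet in ("upper", "lower"):
                labeling = phase_labels(
                    frame, topology, leaflet,
                    eps=config.eps, min_pts=config.min_pts,
                    min_cluster_size=config.min_cluster_size,
                )
                labeling.insert(0, "frame", f)
                labeling.insert(1, "time", frame.time)
                labeling.insert(2, "leaflet", leaflet)
                labeling["regime"] = frame_regime[f]
                phase_rows.append(labeling)
                if leaflet in protein_leaflets and frame_regime[f] is not None:
                    prot_xy = frame.positions[topology.role_mask("protein"), :2]
                    prof = lc_fraction_vs_distance(
                        labeling, prot_xy, frame.box[:2], config.distance_bins
                    )
                    prof["regime"] = frame_regime[f]
                    prof["frame"] = f
                    profile_pool.append(prof)
        phases = pd.concat(phase_rows, ignore_index=True)
        emit("phases.tsv", phases)

        stage = "lc_vs_distance"
        if profile_pool:
            pooled = pd.concat(profile_pool, ignore_index=True)
            pooled["lc_markers"] = pooled["lc_fraction"].fillna(0) * pooled["n_markers"]
            agg = pooled.groupby(["regime", "bin_lo", "bin_hi"], sort=True).agg(
                n_markers=("n_markers", "sum"), lc_markers=("lc_markers", "sum")
            ).reset_index()
            agg["lc_fraction"] = np.where(
                agg["n_markers"] > 0, agg["lc_markers"] / agg["n_markers"], np.nan
            )
            emit("lc_vs_distance.tsv", agg.drop(columns="lc_markers"))
        else:
            report["skipped"]["lc_vs_distance"] = (
                "no protein in the system" if not has_protein else "no frames in any regime"
            )
            logger.info("lc_vs_distance skipped: %s", report["skipped"]["lc_vs_distance"])

        stage = "density"
        dmap = density_profile(
            list(trajectory), topology,
            z_edges=np.asarray(config.z_bins), regimes_per_frame=frame_regime,
        )
        emit("density_map.tsv", dmap.to_table())
        extents = dmap.extents_table()
        extents["thickness"] = extents["z_high"] - extents["z_low"]
        emit("extents.tsv", extents)

        stage = "contacts"
        if has_protein:
            leaflet = next(iter(protein_leaflets))
            per_frame = []
            for frame in trajectory:
                raw = count_contacts(frame, topology, cutoff=config.contact_cutoff)
                per_frame.append(normalize_contacts(raw, topology, leaflet=leaflet))
            strat = stratify_by_regime(per_frame, frame_regime)
            emit("contacts_by_residue.tsv", strat)
            by_type = strat.groupby(["regime", "lipid_type"], sort=True).agg(
                contacts=("contacts", "sum"), normalized=("normalized", "sum")
            ).reset_index()
            emit("contacts_by_type.tsv", by_type)
        else:
            report["skipped"]["contacts"] = "no protein in the system"
            logger.info("contacts skipped: no protein")

        stage = "diffusion"
        diff_rows = []
        for label, frames_idx in _regime_runs(frame_regime):
            if len(frames_idx) < 2:
                continue
            sub = Trajectory(
                times=trajectory.times[frames_idx],
                boxes=trajectory.boxes[frames_idx],
                positions=trajectory.positions[frames_idx],
            )
            span = sub.times[-1] - sub.times[0]
            lag = config.diffusion_lag if span >= config.diffusion_lag else span
            try:
                r = lateral_displacements(
                    sub, topology, lag=lag, drift_correction=config.drift_correction
                )
                est = fit_diffusion(r, _actual_lag(sub.times, lag))
            except ValueError as err:
                logger.info("diffusion: regime %r skipped (%s)", label, err)
                continue
            row = {"regime": label, "system": "run"}
            row.update(est.as_dict())
            diff_rows.append(row)
        if not diff_rows and len(trajectory) >= 2:
            # no regime spans the lag (e.g. one frame per regime): fall back
            # to a single whole-trajectory estimate at the achievable lag
            span = trajectory.times[-1] - trajectory.times[0]
            lag = min(config.diffusion_lag, span)
            try:
                r = lateral_displacements(
                    trajectory, topology, lag=lag, drift_correction=config.drift_correction
                )
                est = fit_diffusion(r, _actual_lag(trajectory.times, lag))
                row = {"regime": "all", "system": "run"}
                row.update(est.as_dict())
                diff_rows.append(row)
                logger.warning(
                    "diffusion: no regime spans the %g ns lag; single estimate over the "
                    "whole trajectory at lag %g ns", config.diffusion_lag, est.lag,
                )
            except ValueError as err:
                logger.info("diffusion fallback failed: %s", err)
        if diff_rows:
            emit("diffusion.tsv", pd.DataFrame(diff_rows))
        else:
            report["skipped"]["diffusion"] = "no regime with enough frames for the lag"

        stage = "rmsd"
        prot_mask = topology.role_mask("protein") if has_protein else None
        if has_protein and int(prot_mask.sum()) >= 3:
            ref = trajectory.positions[0][prot_mask]
            rows = [
                {"frame": f, "time": frame.time, "rmsd": rmsd(frame.positions[prot_mask], ref)}
                for f, frame in enumerate(trajectory)
            ]
            emit("rmsd.tsv", pd.DataFrame(rows))
        else:
            report["skipped"]["rmsd"] = "no protein in the system"

        stage = "report"
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        written.append(out / "report.json")
    except Exception as err:  # noqa: BLE001 - abort cleanly, naming the stage
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, err) from err

    return report


def _actual_lag(times: np.ndarray, lag: float) -> float:
    dt = float(np.median(np.diff(times)))
    return max(1, round(lag / dt)) * dt


def _regime_runs(frame_regime: np.ndarray):
    """Contiguous runs of identical regime labels, as (label, index array)."""
    runs = []
    start = 0
    for i in range(1, len(frame_regime) + 1):
        if i == len(frame_regime) or frame_regime[i] != frame_regime[start]:
            if frame_regime[start] is not None:
                runs.append((str(frame_regime[start]), np.arange(start, i)))
            start = i
    return runs


def _library_versions() -> dict:
    import numpy
    import pandas
    import scipy
    import sklearn

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
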