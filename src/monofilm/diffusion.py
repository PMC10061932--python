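"""Lateral diffusion from displacement distributions.

For free 2D Brownian motion the displacement magnitude r over a lag t
follows

    p(r) = (r / (2 D t)) * exp(-r^2 / (4 D t)),

a Rayleigh density with scale sqrt(2 D t).  The maximum-likelihood estimate
is in closed form,

    D_hat = sum(r_i^2) / (4 t n),        se(D_hat) = D_hat / sqrt(n),

with a Kolmogorov–Smirnov distance against the fitted density reported as a
goodness-of-fit diagnostic.  Displacements are taken over non-overlapping
lag windows (independent samples, so the standard error needs no
autocorrelation correction), on unwrapped tracks, with the leaflet
center-of-mass drift removed by default (the two monolayers of a box can
drift independently).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pbc import minimum_image
from .topology import Topology, Trajectory

__all__ = [
    "DiffusionEstimate",
    "unwrap_trajectory",
    "lateral_displacements",
    "fit_diffusion",
    "relative_diffusion",
    "slowdown_percent",
]

logger = logging.getLogger(__name__)

DEFAULT_LAG = 10.0  # ns


@dataclass(frozen=True)
class DiffusionEstimate:
    """MLE diffusion coefficient with its sampling error and GoF."""

    lag: float  # ns (actual lag used)
    D: float  # nm^2/ns
    se_D: float
    n_displacements: int
    ks_distance: float

    def as_dict(self) -> dict:
        return {
            "lag": self.lag,
            "D": self.D,
            "se_D": self.se_D,
            "n_displacements": self.n_displacements,
            "ks_distance": self.ks_distance,
        }


def unwrap_trajectory(trajectory: Trajectory) -> np.ndarray:
    """Remove periodic jumps from wrapped coordinates.

    Assumes no particle moves further than half a box edge between
    consecutive frames.  Returns positions of the same shape.
    """
    pos = trajectory.positions
    out = pos.copy()
    for f in range(1, len(trajectory)):
        step = minimum_image(pos[f] - pos[f - 1], trajectory.boxes[f])
        out[f] = out[f - 1] + step
    return out


def _reference_tracks(trajectory: Trajectory, topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped xy track per molecule (reference atom) + leaflet label.

    Reference atoms: phosphorus for phospholipids, the hydroxyl oxygen (or
    configured reference atom) for CHOL.  Protein tracks use the heavy-atom
    center of mass and are returned as a single track.
    """
    unwrapped = unwrap_trajectory(trajectory)
    leaflet = topology.atom_leaflet()
    tracks, labels = [], []

    p_mask = topology.role_mask("phosphorus")
    types = topology.atom_lipid_type()
    chol_ref = topology.is_heavy & (types == "CHOL") & (topology.atom_name == "O3")
    ref_mask = p_mask | chol_ref
    for i in np.flatnonzero(ref_mask):
        tracks.append(unwrapped[:, i, :2])
        labels.append(leaflet[i])

    prot_mask = topology.role_mask("protein")
    if prot_mask.any():
        masses = topology.masses()[prot_mask]
        com = np.einsum("fij,i->fj", unwrapped[:, prot_mask, :2], masses) / masses.sum()
        tracks.append(com)
        labels.append(leaflet[np.flatnonzero(prot_mask)[0]])

    return np.stack(tracks, axis=1), np.asarray(labels, dtype=object)  # (F, M, 2)


def lateral_displacements(
    trajectory: Trajectory,
    topology: Topology,
    lag: float = DEFAULT_LAG,
    drift_correction: bool = True,
    leaflet: str | None = None,
) -> np.ndarray:
    """2D displacement magnitudes over non-overlapping lag windows (nm).

    The lag is rounded to the nearest whole number of frame intervals; the
    actual lag used is logged when it differs from the request.
    """
    times = trajectory.times
    if len(trajectory) < 2:
        raise ValueError("trajectory needs at least two frames")
    dt = float(np.median(np.diff(times)))
    span = times[-1] - times[0]
    if span < lag:
        raise ValueError(f"trajectory span {span} ns is shorter than the lag {lag} ns")
    stride = max(1, round(lag / dt))
    actual = stride * dt
    if abs(actual - lag) > 1e-9:
        logger.info("lateral_displacements: frame spacing %g ns; using actual lag %g ns", dt, actual)

    tracks, labels = _reference_tracks(trajectory, topology)
    if leaflet is not None:
        tracks = tracks[:, labels == leaflet, :]
        labels = labels[labels == leaflet]

    if drift_correction:
        for side in np.unique(labels):
            sel = labels == side
            drift = tracks[:, sel, :].mean(axis=1, keepdims=True)
            tracks[:, sel, :] = tracks[:, sel, :] - (drift - drift[0])

    starts = np.arange(0, tracks.shape[0] - stride, stride)
    disp = tracks[starts + stride] - tracks[starts]  # (W, M, 2)
    return np.linalg.norm(disp, axis=-1).ravel()


def fit_diffusion(displacements: np.ndarray, lag: float) -> DiffusionEstimate:
    """Closed-form MLE of D from 2D displacement magnitudes."""
    r = np.asarray(displacements, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 displacements")
    if lag <= 0:
        raise ValueError("lag must be positive")
    if np.any(r < 0):
        raise ValueError("displacement magnitudes must be nonnegative")

    d_hat = float(np.sum(r**2) / (4.0 * lag * r.size))
    se = d_hat / math.sqrt(r.size)
    if d_hat > 0:
        ks = float(stats.kstest(r, stats.rayleigh(scale=math.sqrt(2 * d_hat * lag)).cdf).statistic)
    else:
        ks = 0.0 if np.all(r == 0) else 1.0
    return DiffusionEstimate(
        lag=float(lag), D=d_hat, se_D=se, n_displacements=int(r.size), ks_distance=ks
    )


def relative_diffusion(
    estimates: pd.DataFrame,
    reference_regime: str = "0-15 mN/m",
    group_col: str = "system",
) -> pd.DataFrame:
    """Normalize D to unity at the reference regime, per system.

    ``estimates`` is tidy with at least columns ``regime``, ``D`` and
    ``group_col``.
    """
    out = estimates.copy()
    out["D_relative"] = np.nan
    for system, group in estimates.groupby(group_col):
        ref = group.loc[group["regime"] == reference_regime, "D"]
        if ref.empty:
            raise ValueError(f"system {system!r}: reference regime {reference_regime!r} is empty")
        ref_d = float(ref.mean())
        if ref_d == 0:
            raise ValueError(f"system {system!r}: reference-regime D is zero")
        out.loc[group.index, "D_relative"] = group["D"] / ref_d
    return out


def slowdown_percent(D_protein: float, D_reference: float) -> float:
    """Percent slowdown of diffusion relative to a reference (negative = speedup)."""
    if D_reference <= 0:
        raise ValueError("reference D must be positive")
    return 100.0 * (1.0 - D_protein / D_reference)
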