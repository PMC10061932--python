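"""Surface tension, surface pressure, area per lipid, and nonequilibrium
windowed isotherms.

For a slab with ``n`` planar interfaces normal to z, the surface tension in
mN/m follows from the pressure-tensor anisotropy (bar) and the box height
(nm):

    gamma = 0.1 * (Lz / n) * (Pzz - (Pxx + Pyy) / 2)

(1 bar·nm = 0.1 mN/m).  Monolayer simulation boxes contain two air–water
interfaces, hence the default ``n_interfaces=2``.  Surface pressure is the
drop of the clean-interface tension: Pi = gamma0 - gamma.

Compression runs are out of equilibrium, so isotherms are extracted by
binning APL and Pi into consecutive non-overlapping time windows (100 ns by
default) and reporting per-window means with their standard errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import PressureSeries

__all__ = [
    "GAMMA0_298K",
    "GAMMA0_310K",
    "PressureRegime",
    "DEFAULT_REGIMES",
    "surface_tension",
    "surface_pressure",
    "area_per_lipid",
    "windowed_isotherm",
    "isotherm_from_series",
    "isotherm_shift",
    "regime_of",
]

logger = logging.getLogger(__name__)

#: experimental clean water–air surface tensions (mN/m)
GAMMA0_298K = 71.7
GAMMA0_310K = 69.4


@dataclass(frozen=True)
class PressureRegime:
    """Half-open surface-pressure stratification bin [lower, upper) in mN/m."""

    label: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"regime {self.label!r}: lower must be < upper")

    def contains(self, pi: float | np.ndarray) -> np.ndarray:
        return (np.asarray(pi) >= self.lower) & (np.asarray(pi) < self.upper)


DEFAULT_REGIMES = (
    PressureRegime("0-15 mN/m", 0.0, 15.0),
    PressureRegime("15-30 mN/m", 15.0, 30.0),
    PressureRegime("30-45 mN/m", 30.0, 45.0),
    PressureRegime(">45 mN/m", 45.0, math.inf),
)


def _validate_regimes(regimes: tuple[PressureRegime, ...]) -> None:
    ordered = sorted(regimes, key=lambda r: r.lower)
    for a, b in zip(ordered, ordered[1:]):
        if b.lower < a.upper:
            raise ValueError(f"regimes {a.label!r} and {b.label!r} overlap")


def regime_of(pi: np.ndarray, regimes: tuple[PressureRegime, ...] = DEFAULT_REGIMES) -> np.ndarray:
    """Regime label per sample; None where Pi falls outside all regimes."""
    _validate_regimes(tuple(regimes))
    pi = np.asarray(pi, dtype=float)
    labels = np.full(pi.shape, None, dtype=object)
    for regime in regimes:
        labels[regime.contains(pi)] = regime.label
    return labels


def surface_tension(
    Pxx: np.ndarray,
    Pyy: np.ndarray,
    Pzz: np.ndarray,
    Lz: np.ndarray,
    n_interfaces: int = 2,
) -> np.ndarray:
    """Surface tension (mN/m) from pressure components (bar) and box height (nm)."""
    if n_interfaces not in (1, 2):
        raise ValueError(f"n_interfaces must be 1 or 2, got {n_interfaces}")
    Pxx, Pyy, Pzz, Lz = (np.asarray(a, dtype=float) for a in (Pxx, Pyy, Pzz, Lz))
    return 0.1 * (Lz / n_interfaces) * (Pzz - 0.5 * (Pxx + Pyy))


def surface_pressure(gamma: np.ndarray, gamma0: float) -> np.ndarray:
    """Surface pressure Pi = gamma0 - gamma (mN/m); negative values pass through."""
    if gamma0 <= 0:
        raise ValueError(f"gamma0 must be positive, got {gamma0}")
    pi = gamma0 - np.asarray(gamma, dtype=float)
    n_neg = int(np.sum(pi < 0))
    if n_neg:
        logger.info("surface_pressure: %d samples with negative Pi (gamma > gamma0)", n_neg)
    return pi


def area_per_lipid(Lx: np.ndarray, Ly: np.ndarray, n_lipids_per_leaflet: int) -> np.ndarray:
    """APL in Å² from box edges in nm.  Protein area is never subtracted."""
    if n_lipids_per_leaflet < 1:
        raise ValueError("n_lipids_per_leaflet must be >= 1")
    return 100.0 * np.asarray(Lx, dtype=float) * np.asarray(Ly, dtype=float) / n_lipids_per_leaflet


def windowed_isotherm(
    times: np.ndarray,
    apl_series: np.ndarray,
    pi_series: np.ndarray,
    window: float = 100.0,
) -> pd.DataFrame:
    """Bin APL and Pi into consecutive non-overlapping time windows.

    Returns a tidy table with one row per window: ``window_center_time`` (ns),
    ``apl_mean``/``apl_sd`` (Å²), ``pi_mean``/``pi_se`` (mN/m), ``n_samples``,
    and ``partial`` flagging a trailing window shorter than ``window``.
    """
    times = np.asarray(times, dtype=float)
    apl_series = np.asarray(apl_series, dtype=float)
    pi_series = np.asarray(pi_series, dtype=float)
    if times.size == 0:
        raise ValueError("empty time series")
    if not (times.size == apl_series.size == pi_series.size):
        raise ValueError("times, APL and Pi series must be aligned")
    if window <= 0:
        raise ValueError("window must be positive")

    t0 = times[0]
    span = times[-1] - t0
    n_windows = max(1, math.ceil(span / window)) if span > 0 else 1
    idx = np.minimum(((times - t0) / window).astype(int), n_windows - 1)

    records = []
    for w in range(n_windows):
        sel = idx == w
        n = int(sel.sum())
        if n == 0:
            continue
        apl_w = apl_series[sel]
        pi_w = pi_series[sel]
        apl_sd = float(apl_w.std(ddof=1)) if n > 1 else 0.0
        pi_sd = float(pi_w.std(ddof=1)) if n > 1 else 0.0
        is_partial = (t0 + (w + 1) * window) > times[-1] + 1e-12 and w == n_windows - 1
        records.append(
            {
                "window_center_time": t0 + (w + 0.5) * window,
                "apl_mean": float(apl_w.mean()),
                "apl_sd": apl_sd,
                "pi_mean": float(pi_w.mean()),
                "pi_se": pi_sd / math.sqrt(n),
                "n_samples": n,
                "partial": bool(is_partial),
            }
        )
    return pd.DataFrame.from_records(records)


def isotherm_from_series(
    series: PressureSeries,
    gamma0: float,
    n_interfaces: int = 2,
    window: float = 100.0,
) -> pd.DataFrame:
    """Windowed Pi–APL isotherm straight from a pressure-tensor series."""
    if series.apl is None:
        raise ValueError("pressure series carries no APL column")
    gamma = surface_tension(series.Pxx, series.Pyy, series.Pzz, series.Lz, n_interfaces)
    pi = surface_pressure(gamma, gamma0)
    return windowed_isotherm(series.time, series.apl, pi, window)


def isotherm_shift(
    iso_ref: pd.DataFrame,
    iso_test: pd.DataFrame,
    apl_range: tuple[float, float] = (50.0, 85.0),
    n_grid: int = 50,
) -> tuple[float, float]:
    """Mean vertical offset between two isotherms over a common APL range.

    Both isotherms are linearly interpolated in APL onto a shared grid over
    the overlap of ``apl_range`` with the two measured APL ranges; the shift
    is the grid mean of (Pi_test - Pi_ref).  The standard error combines the
    per-window SEs of both curves and scales with the number of independent
    windows inside the range (grid points oversample the same windows and are
    not counted as independent).  With replica curves, call per replica and
    combine the shifts; their spread is the between-replica error.

    Returns ``(delta_mean, delta_se)`` in mN/m.
    """
    lo = max(apl_range[0], iso_ref["apl_mean"].min(), iso_test["apl_mean"].min())
    hi = min(apl_range[1], iso_ref["apl_mean"].max(), iso_test["apl_mean"].max())
    if not lo < hi:
        raise ValueError(
            f"isotherms do not overlap within APL range {apl_range} "
            f"(effective overlap [{lo:.1f}, {hi:.1f}] Å²)"
        )
    grid = np.linspace(lo, hi, n_grid)

    def interp(iso: pd.DataFrame, col: str) -> np.ndarray:
        order = np.argsort(iso["apl_mean"].to_numpy())
        x = iso["apl_mean"].to_numpy()[order]
        y = iso[col].to_numpy()[order]
        return np.interp(grid, x, y)

    in_ref = (iso_ref["apl_mean"] >= lo) & (iso_ref["apl_mean"] <= hi)
    in_test = (iso_test["apl_mean"] >= lo) & (iso_test["apl_mean"] <= hi)
    if int(in_ref.sum()) < 3 or int(in_test.sum()) < 3:
        raise ValueError(
            "insufficient overlap: need >= 3 isotherm windows from each curve "
            f"inside [{lo:.1f}, {hi:.1f}] Å²"
        )

    delta = interp(iso_test, "pi_mean") - interp(iso_ref, "pi_mean")
    se_grid = np.sqrt(interp(iso_test, "pi_se") ** 2 + interp(iso_ref, "pi_se") ** 2)
    n_eff = min(int(in_ref.sum()), int(in_test.sum()))
    return float(delta.mean()), float(se_grid.mean() / math.sqrt(n_eff))
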