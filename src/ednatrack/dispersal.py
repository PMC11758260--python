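"""Dispersal products from backtracked trajectories.

Turns trajectory sets into the quantities used to interpret eDNA
detections: percentage-occupancy density heatmaps on a 1 km grid, maximum
straight-line dispersal distances, areal extents of the visited region,
and inter-station connectivity fractions (how often water sampled at one
station passed near another within the decay window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flowfields import GridSpec
from .tracker import TrajectorySet

__all__ = [
    "DensityGrid",
    "DispersalStats",
    "ConnectivityMatrix",
    "density_heatmap",
    "max_straight_line_distance",
    "areal_extent",
    "aggregate_dispersal",
    "connectivity",
]


class DispersalError(ValueError):
    pass


@dataclass
class DensityGrid:
    """Percentage of all particle-records per half-open 1 km^2 cell.

    Every record of every particle is counted — beached and out-of-domain
    particles stay frozen at their last valid position and keep
    contributing — so the densities over the whole grid sum to exactly
    100 when any contributions exist.
    """

    grid: GridSpec
    density: np.ndarray  # (n_y, n_x) percent
    n_contributions: int

    def total(self) -> float:
        return float(self.density.sum())


@dataclass
class DispersalStats:
    """Aggregate dispersal over a set of releases (mean / sample sd, n-1).

    ``sd`` entries are NaN when fewer than two releases are aggregated.
    """

    per_release: pd.DataFrame  # columns: station_id, sample_time, max_distance_km, areal_extent_km2
    mean_max_distance_km: float
    sd_max_distance_km: float
    mean_areal_extent_km2: float
    sd_areal_extent_km2: float


@dataclass
class ConnectivityMatrix:
    """fraction[i, j]: share of particles backtracked from station i that
    ever pass within ``radius`` of station j during the window."""

    station_ids: list
    fraction: np.ndarray  # (n, n)
    radius: float

    def potentially_connected(self) -> np.ndarray:
        """Boolean any-visit view (fraction > 0)."""
        return self.fraction > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fraction, index=self.station_ids, columns=self.station_ids)


def _all_positions(traj_sets: list[TrajectorySet]) -> tuple[np.ndarray, np.ndarray]:
    xs = np.concatenate([t.positions[:, :, 0].ravel() for t in traj_sets])
    ys = np.concatenate([t.positions[:, :, 1].ravel() for t in traj_sets])
    return xs, ys


def density_heatmap(traj_sets: list[TrajectorySet], grid: GridSpec) -> DensityGrid:
    """Count every particle-record into the grid and convert to percent.

    The grid is auto-expanded (keeping its origin lattice) when recorded
    positions fall outside it, so no contribution is ever dropped and the
    total is 100% by construction.
    """
    if not traj_sets:
        raise DispersalError("density_heatmap requires at least one trajectory set")
    xs, ys = _all_positions(traj_sets)
    grid = grid.expanded_to_cover(xs, ys)
    ix, iy = grid.cell_indices(xs, ys)
    counts = np.zeros((grid.n_y, grid.n_x), dtype=np.int64)
    np.add.at(counts, (iy, ix), 1)
    n = xs.size
    return DensityGrid(grid=grid, density=counts * (100.0 / n), n_contributions=int(n))


def max_straight_line_distance(traj: TrajectorySet) -> float:
    """Maximum Euclidean distance (km) of any particle-record from the station."""
    dx = traj.positions[:, :, 0] - traj.station_x
    dy = traj.positions[:, :, 1] - traj.station_y
    return float(np.sqrt(np.max(dx * dx + dy * dy)) / 1000.0)


def areal_extent(traj_sets: list[TrajectorySet], grid: GridSpec) -> float:
    """Area (km^2) of the union of grid cells visited by any particle-record."""
    if not traj_sets:
        raise DispersalError("areal_extent requires at least one trajectory set")
    xs, ys = _all_positions(traj_sets)
    grid = grid.expanded_to_cover(xs, ys)
    ix, iy = grid.cell_indices(xs, ys)
    n_cells = np.unique(iy.astype(np.int64) * grid.n_x + ix).size
    return float(n_cells) * grid.cell_area_km2


def aggregate_dispersal(
    per_release: pd.DataFrame,
    detection_filter=None,
) -> DispersalStats:
    """Mean and sample sd of dispersal metrics over detection-coincident releases.

    Parameters
    ----------
    per_release : DataFrame
        One row per release with columns ``station_id``, ``sample_time``
        (or ``month``), ``max_distance_km``, ``areal_extent_km2``.
    detection_filter : callable or boolean mask, optional
        Selects the releases that coincide with eDNA detections; the
        aggregate is taken over those only.  ``None`` keeps all releases.
    """
    df = per_release
    if detection_filter is not None:
        if callable(detection_filter):
            mask = df.apply(detection_filter, axis=1).astype(bool)
        else:
            mask = np.asarray(detection_filter, dtype=bool)
        df = df.loc[mask]
    if len(df) == 0:
        raise DispersalError("detection filter selected no releases")
    d = df["max_distance_km"].to_numpy(dtype=float)
    a = df["areal_extent_km2"].to_numpy(dtype=float)
    sd = lambda v: float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")
    return DispersalStats(
        per_release=df.reset_index(drop=True),
        mean_max_distance_km=float(d.mean()),
        sd_max_distance_km=sd(d),
        mean_areal_extent_km2=float(a.mean()),
        sd_areal_extent_km2=sd(a),
    )


def connectivity(
    traj_by_station: dict[str, TrajectorySet],
    stations,
    radius: float = 1000.0,
) -> ConnectivityMatrix:
    """Any-visit connectivity fractions between stations.

    ``fraction[i, j]`` is the share of particles backtracked from station i
    with at least one record within ``radius`` metres of station j.  The
    diagonal is 1 whenever the release radius does not exceed ``radius``
    (the elapsed-0 record sits inside the release disc).
    """
    pos = {s.id: (s.x, s.y) for s in stations}
    ids = [s.id for s in stations]
    missing = [sid for sid in ids if sid not in traj_by_station]
    if missing:
        raise DispersalError(f"missing trajectory sets for stations: {', '.join(missing)}")
    n = len(ids)
    frac = np.zeros((n, n))
    r2 = radius * radius
    for i, sid in enumerate(ids):
        traj = traj_by_station[sid]
        x = traj.positions[:, :, 0]
        y = traj.positions[:, :, 1]
        for j, tid in enumerate(ids):
            tx, ty = pos[tid]
            d2 = (x - tx) ** 2 + (y - ty) ** 2
            visited = (d2 <= r2).any(axis=1)
            frac[i, j] = visited.mean()
    return ConnectivityMatrix(station_ids=ids, fraction=frac, radius=radius)
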