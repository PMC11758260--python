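"""Depth-averaged velocity fields on regular grids.

Coastal eDNA transport is driven by tidal, depth-averaged currents.  This
module holds the gridded velocity container (:class:`FlowField`), bilinear
space / linear time interpolation with wet/dry handling, the time-reversal
operator that turns a forward hindcast into a backtracking field, and
netCDF I/O.

Coordinates are local projected metres (easting/northing): distances and
areas come out directly in km and km² without geodesic corrections.
``lonlat_to_xy`` converts geographic positions via an equirectangular
projection about a reference latitude for users starting from lon/lat.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr

__all__ = [
    "FlowField",
    "GridSpec",
    "FlowFieldError",
    "DomainError",
    "FormatError",
    "sample_velocity",
    "reverse_field",
    "read_flowfield",
    "write_flowfield",
    "is_wet",
    "lonlat_to_xy",
]

_EARTH_RADIUS_M = 6_371_000.0


class FlowFieldError(ValueError):
    """Invalid flow-field construction or use."""


class DomainError(FlowFieldError):
    """Position or time outside the field's domain."""


class FormatError(FlowFieldError):
    """Malformed flow-field file."""


@dataclass
class FlowField:
    """Time-varying 2-D depth-averaged currents on a regular node grid.

    Parameters
    ----------
    x_coords, y_coords : 1-D float arrays, strictly increasing
        Node eastings / northings in metres.
    times : 1-D float array, strictly increasing, uniformly spaced
        Seconds since the simulation epoch.
    u, v : float arrays of shape (time, y, x)
        Eastward / northward velocity in m/s at the nodes.
    wet_mask : bool array of shape (y, x)
        True where the node is water.  Velocities at dry nodes are
        ignored by interpolation (weights renormalised over wet corners).
    """

    x_coords: np.ndarray
    y_coords: np.ndarray
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    wet_mask: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x_coords = np.asarray(self.x_coords, dtype=float)
        self.y_coords = np.asarray(self.y_coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.wet_mask is None:
            self.wet_mask = np.ones((self.y_coords.size, self.x_coords.size), dtype=bool)
        self.wet_mask = np.asarray(self.wet_mask, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        for name, arr in (("x", self.x_coords), ("y", self.y_coords), ("time", self.times)):
            if arr.ndim != 1 or arr.size < 2:
                raise FlowFieldError(f"{name} coordinates must be 1-D with at least 2 entries")
            if not np.all(np.diff(arr) > 0):
                raise FlowFieldError(f"{name} coordinates must be strictly increasing")
        shape = (self.times.size, self.y_coords.size, self.x_coords.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise FlowFieldError(
                f"u/v shapes {self.u.shape}/{self.v.shape} inconsistent with "
                f"coordinate lengths {shape}"
            )
        if self.wet_mask.shape != shape[1:]:
            raise FlowFieldError(
                f"wet_mask shape {self.wet_mask.shape} does not match (y, x) = {shape[1:]}"
            )
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=0.0):
            raise FlowFieldError("time spacing must be uniform (1e-6 relative tolerance)")
        wet = self.wet_mask
        if not (np.all(np.isfinite(self.u[:, wet])) and np.all(np.isfinite(self.v[:, wet]))):
            raise FlowFieldError("u and v must be finite at all wet nodes for all times")

    # -- convenience ---------------------------------------------------
    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the node bounding box."""
        return (
            float(self.x_coords[0]),
            float(self.x_coords[-1]),
            float(self.y_coords[0]),
            float(self.y_coords[-1]),
        )

    @property
    def time_span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class GridSpec:
    """Regular analysis grid of half-open cells [origin + i*cell, origin + (i+1)*cell).

    Default cell size is 1000 m: dispersal products are tallied on a
    1 x 1 km grid.
    """

    origin_x: float
    origin_y: float
    n_x: int
    n_y: int
    cell_size: float = 1000.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("n_x and n_y must be >= 1")

    def cell_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Column/row indices of the half-open cells containing (x, y)."""
        ix = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        return ix, iy

    def expanded_to_cover(self, x: np.ndarray, y: np.ndarray) -> "GridSpec":
        """Smallest grid with the same origin lattice covering all points."""
        ix, iy = self.cell_indices(x, y)
        ox = self.origin_x + min(0, int(ix.min())) * self.cell_size
        oy = self.origin_y + min(0, int(iy.min())) * self.cell_size
        nx = int(ix.max()) - min(0, int(ix.min())) + 1
        ny = int(iy.max()) - min(0, int(iy.min())) + 1
        return GridSpec(ox, oy, max(nx, self.n_x), max(ny, self.n_y), self.cell_size)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2


def lonlat_to_xy(lon, lat, lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection of lon/lat (degrees) to local metres.

    Adequate at bay scale (tens of km), where the metric distortion about
    the reference latitude ``lat0`` is negligible.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = np.radians(lon - lon0) * _EARTH_RADIUS_M * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * _EARTH_RADIUS_M
    return x, y


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _bracket(coords: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Left index and fractional offset of ``values`` in node array ``coords``."""
    idx = np.clip(np.searchsorted(coords, values, side="right") - 1, 0, coords.size - 2)
    frac = (values - coords[idx]) / (coords[idx + 1] - coords[idx])
    return idx, frac


def _sample_many(
    field: FlowField,
    x: np.ndarray,
    y: np.ndarray,
    t: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised bilinear/linear-time sampling; out-of-bounds points get (0, 0).

    Dry corner nodes contribute zero velocity and their bilinear weights are
    renormalised over the wet corners; all-dry quads return (0, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x0, x1, y0, y1 = field.bounds
    inb = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)

    ti, tf = _bracket(field.times, np.asarray(t, dtype=float))
    ti = int(ti)
    tf = float(tf)
    # linear interpolation in time of the two bracketing snapshots
    u_t = (1.0 - tf) * field.u[ti] + tf * field.u[ti + 1]
    v_t = (1.0 - tf) * field.v[ti] + tf * field.v[ti + 1]

    xc = np.where(inb, x, x0)
    yc = np.where(inb, y, y0)
    ix, fx = _bracket(field.x_coords, xc)
    iy, fy = _bracket(field.y_coords, yc)

    w00 = (1 - fx) * (1 - fy)
    w10 = fx * (1 - fy)
    w01 = (1 - fx) * fy
    w11 = fx * fy

    m = field.wet_mask
    m00 = m[iy, ix]
    m10 = m[iy, ix + 1]
    m01 = m[iy + 1, ix]
    m11 = m[iy + 1, ix + 1]

    w00 = w00 * m00
    w10 = w10 * m10
    w01 = w01 * m01
    w11 = w11 * m11
    wsum = w00 + w10 + w01 + w11
    scale = np.where(wsum > 0, 1.0 / np.where(wsum > 0, wsum, 1.0), 0.0)

    u = (w00 * u_t[iy, ix] + w10 * u_t[iy, ix + 1] + w01 * u_t[iy + 1, ix] + w11 * u_t[iy + 1, ix + 1]) * scale
    v = (w00 * v_t[iy, ix] + w10 * v_t[iy, ix + 1] + w01 * v_t[iy + 1, ix] + w11 * v_t[iy + 1, ix + 1]) * scale
    u = np.where(inb, u, 0.0)
    v = np.where(inb, v, 0.0)
    return u, v


def sample_velocity(field: FlowField, x: float, y: float, t: float) -> tuple[float, float]:
    """Velocity (u, v) in m/s at position (x, y) metres and time t seconds.

    Bilinear in space, linear in time.  Dry corners contribute zero velocity
    with weights renormalised over wet corners; if all four corners are dry
    the velocity is (0, 0).

    Raises
    ------
    DomainError
        If the position is outside the coordinate bounding box or the time
        is outside the field's time span; the message names the axis.
    """
    x0, x1, y0, y1 = field.bounds
    t0, t1 = field.time_span
    if not (x0 <= x <= x1):
        raise DomainError(f"x = {x} outside domain [{x0}, {x1}] on axis 'x'")
    if not (y0 <= y <= y1):
        raise DomainError(f"y = {y} outside domain [{y0}, {y1}] on axis 'y'")
    if not (t0 <= t <= t1):
        raise DomainError(f"t = {t} outside time span [{t0}, {t1}] on axis 'time'")
    u, v = _sample_many(field, np.array([x]), np.array([y]), float(t))
    return float(u[0]), float(v[0])


def reverse_field(field: FlowField) -> FlowField:
    """Time-reverse a field so backtracking becomes forward integration.

    The returned field has times ``t'_k = times[-1] - times[n-1-k]``
    (reversed order, re-anchored at 0) and negated, time-reversed
    velocities.  The wet mask is unchanged.  Advecting forward in the
    reversed field is equivalent to advecting backwards in the original.
    """
    times_rev = field.times[-1] - field.times[::-1]
    return FlowField(
        x_coords=field.x_coords.copy(),
        y_coords=field.y_coords.copy(),
        times=times_rev,
        u=-field.u[::-1].copy(),
        v=-field.v[::-1].copy(),
        wet_mask=field.wet_mask.copy(),
    )


def is_wet(field: FlowField, x: float, y: float) -> bool:
    """True iff (x, y) falls in a wet cell; out-of-domain points are dry.

    Each node owns the cell of one grid spacing centred on it, so the test
    is against the nearest node's wet flag.
    """
    wet = _is_wet_many(field, np.asarray([x], dtype=float), np.asarray([y], dtype=float))
    return bool(wet[0])


def _is_wet_many(field: FlowField, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x0, x1, y0, y1 = field.bounds
    inb = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    xc = np.where(inb, x, x0)
    yc = np.where(inb, y, y0)
    ix, fx = _bracket(field.x_coords, xc)
    iy, fy = _bracket(field.y_coords, yc)
    ix = ix + (fx >= 0.5)
    iy = iy + (fy >= 0.5)
    return inb & field.wet_mask[iy, ix]


# ---------------------------------------------------------------------------
# I/O  (CF-style netCDF; scipy backend, netCDF3 64-bit offset)
# ---------------------------------------------------------------------------

_REQUIRED_VARS = ("x", "y", "time", "u", "v", "wet_mask")


def write_flowfield(field: FlowField, path) -> None:
    """Write a FlowField to netCDF.

    Dialect: dims ``time``, ``y``, ``x``; variables ``x(x)`` [m], ``y(y)``
    [m], ``time(time)`` [s since epoch], ``u(time,y,x)`` and ``v(time,y,x)``
    [m s-1] stored as float32, ``wet_mask(y,x)`` as 0/1 byte.
    """
    ds = xr.Dataset(
        {
            "u": (("time", "y", "x"), field.u.astype(np.float32), {"units": "m s-1"}),
            "v": (("time", "y", "x"), field.v.astype(np.float32), {"units": "m s-1"}),
            "wet_mask": (("y", "x"), field.wet_mask.astype(np.int8), {"flag_meanings": "dry wet"}),
        },
        coords={
            "x": ("x", field.x_coords, {"units": "m", "standard_name": "projection_x_coordinate"}),
            "y": ("y", field.y_coords, {"units": "m", "standard_name": "projection_y_coordinate"}),
            "time": ("time", field.times, {"units": "s"}),
        },
    )
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def read_flowfield(path) -> FlowField:
    """Read a FlowField written by :func:`write_flowfield`.

    Raises
    ------
    FormatError
        If a required variable is missing, shapes are inconsistent, or
        coordinates are non-monotone; the message names the violation.
    """
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        missing = [name for name in _REQUIRED_VARS if name not in ds.variables]
        if missing:
            raise FormatError(f"flow-field file missing variable(s): {', '.join(missing)}")
        try:
            return FlowField(
                x_coords=ds["x"].values.astype(float),
                y_coords=ds["y"].values.astype(float),
                times=ds["time"].values.astype(float),
                u=ds["u"].values.astype(float),
                v=ds["v"].values.astype(float),
                wet_mask=ds["wet_mask"].values.astype(bool),
            )
        except FlowFieldError as exc:
            raise FormatError(str(exc)) from exc
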