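"""Passive Lagrangian particle advection and station backtracking.

Implements the release protocol used for eDNA source-area estimation:
particles are seeded uniformly over a disc around the sampling station,
advected passively (no diffusion) through the depth-averaged currents with
fixed-step RK4, and recorded at regular intervals.  Backtracking runs the
same integrator forward through the time-reversed field, so that every
particle arrives at the station at the exact sampling time and the
trajectory traces where the sampled water — and the eDNA in it — could
have come from over the preceding decay window.

Defaults follow the field protocol: 1000 particles, 200 m release radius,
3-day window (a hard proxy for eDNA degradation), 5-minute recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from .flowfields import FlowField, _is_wet_many, _sample_many, reverse_field

__all__ = [
    "Station",
    "ReleaseSpec",
    "TrajectorySet",
    "STATUS_ACTIVE",
    "STATUS_BEACHED",
    "STATUS_OUT_OF_DOMAIN",
    "release_positions",
    "advect",
    "backtrack",
    "read_stations",
    "read_sampling_times",
    "write_trajectories",
    "read_trajectories",
]

STATUS_ACTIVE = 0
STATUS_BEACHED = 1
STATUS_OUT_OF_DOMAIN = 2

_STATUS_NAMES = {STATUS_ACTIVE: "active", STATUS_BEACHED: "beached", STATUS_OUT_OF_DOMAIN: "out_of_domain"}


class TrackerError(ValueError):
    pass


class ConfigurationError(TrackerError):
    """Field coverage or spec arithmetic does not support the requested run."""


@dataclass(frozen=True)
class Station:
    """A sampling station: short code, planar position, sampling times (s since epoch)."""

    id: str
    x: float
    y: float
    sampling_times: tuple = ()

    def __post_init__(self) -> None:
        st = tuple(float(t) for t in self.sampling_times)
        if any(b <= a for a, b in zip(st, st[1:])):
            raise TrackerError(f"station {self.id}: sampling_times must be strictly increasing")
        object.__setattr__(self, "sampling_times", st)


@dataclass(frozen=True)
class ReleaseSpec:
    """Release and integration parameters for one backtracking run.

    ``duration`` is the decay-window proxy: particles older than this are
    assumed undetectable, so trajectories stop there.  ``dt`` must divide
    ``record_interval`` which must divide ``duration``.
    """

    n_particles: int = 1000
    radius: float = 200.0
    duration: float = 259_200.0  # 3 days
    record_interval: float = 300.0  # 5 min
    dt: float = 60.0
    seed: int = 0
    diffusivity: float = 0.0  # m^2/s; optional random-walk mixing, off by default

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise TrackerError("n_particles must be >= 1")
        if self.radius < 0:
            raise TrackerError("radius must be >= 0")
        if self.dt <= 0 or self.record_interval <= 0 or self.duration <= 0:
            raise TrackerError("dt, record_interval and duration must be positive")
        if abs(round(self.record_interval / self.dt) * self.dt - self.record_interval) > 1e-9:
            raise TrackerError("dt must divide record_interval")
        if abs(round(self.duration / self.record_interval) * self.record_interval - self.duration) > 1e-9:
            raise TrackerError("record_interval must divide duration")

    @property
    def n_records(self) -> int:
        return int(round(self.duration / self.record_interval)) + 1


@dataclass
class TrajectorySet:
    """Recorded particle positions for one release.

    ``elapsed`` is seconds *before* the sampling time for backtracked runs
    (0, record_interval, ..., duration); for plain forward runs it is time
    since release.  ``status`` is per particle per record; once a particle
    beaches or leaves the domain its status never reverts and its position
    stays frozen at the last valid location.
    """

    station_id: str
    sample_time: float
    elapsed: np.ndarray  # (n_records,)
    positions: np.ndarray  # (n_particles, n_records, 2) metres
    status: np.ndarray  # (n_particles, n_records) int8
    station_x: float = 0.0
    station_y: float = 0.0

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_records(self) -> int:
        return self.positions.shape[1]


def release_positions(station: Station, spec: ReleaseSpec) -> np.ndarray:
    """Seed positions uniform over the release disc around the station.

    Uses the sqrt-uniform radial transform (r = R*sqrt(U), theta = 2*pi*U')
    for uniform areal density.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.radius * np.sqrt(rng.random(spec.n_particles))
    theta = 2.0 * np.pi * rng.random(spec.n_particles)
    pos = np.empty((spec.n_particles, 2))
    pos[:, 0] = station.x + r * np.cos(theta)
    pos[:, 1] = station.y + r * np.sin(theta)
    return pos


def _rk4_step(field: FlowField, x: np.ndarray, y: np.ndarray, t: float, dt: float):
    u1, v1 = _sample_many(field, x, y, t)
    u2, v2 = _sample_many(field, x + 0.5 * dt * u1, y + 0.5 * dt * v1, t + 0.5 * dt)
    u3, v3 = _sample_many(field, x + 0.5 * dt * u2, y + 0.5 * dt * v2, t + 0.5 * dt)
    u4, v4 = _sample_many(field, x + dt * u3, y + dt * v3, t + dt)
    nx = x + dt / 6.0 * (u1 + 2 * u2 + 2 * u3 + u4)
    ny = y + dt / 6.0 * (v1 + 2 * v2 + 2 * v3 + v4)
    return nx, ny


def advect(
    field: FlowField,
    positions: np.ndarray,
    t_start: float,
    spec: ReleaseSpec,
    station_id: str = "",
    station_xy: tuple[float, float] | None = None,
) -> TrajectorySet:
    """Integrate particles forward from ``t_start`` for ``spec.duration``.

    Fixed-step RK4 through the interpolated velocity field; purely passive
    unless ``spec.diffusivity`` adds a random-walk term.  Particles that
    step onto land are flagged beached; particles leaving the bounding box
    are flagged out of domain.  Both are frozen at their last valid
    position but keep contributing records (particle counts are conserved
    for the density normalisation downstream).
    """
    t0, t1 = field.time_span
    if t_start < t0 - 1e-9 or t_start + spec.duration > t1 + 1e-9:
        raise ConfigurationError(
            f"field time span [{t0}, {t1}] does not cover the run "
            f"[{t_start}, {t_start + spec.duration}]"
        )
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    x = positions[:, 0].copy()
    y = positions[:, 1].copy()
    n_rec = spec.n_records
    steps_per_rec = int(round(spec.record_interval / spec.dt))

    out = np.empty((n, n_rec, 2))
    status = np.zeros((n, n_rec), dtype=np.int8)
    cur_status = np.zeros(n, dtype=np.int8)
    # entry state: particles seeded on land / out of the box are flagged at once
    x0b, x1b, y0b, y1b = field.bounds
    inb = (x >= x0b) & (x <= x1b) & (y >= y0b) & (y <= y1b)
    cur_status[~inb] = STATUS_OUT_OF_DOMAIN
    wet = _is_wet_many(field, x, y)
    cur_status[inb & ~wet] = STATUS_BEACHED

    out[:, 0, 0] = x
    out[:, 0, 1] = y
    status[:, 0] = cur_status

    rng = np.random.default_rng(spec.seed + 1) if spec.diffusivity > 0 else None
    t = float(t_start)
    for rec in range(1, n_rec):
        for _ in range(steps_per_rec):
            active = cur_status == STATUS_ACTIVE
            if active.any():
                nx, ny = _rk4_step(field, x[active], y[active], t, spec.dt)
                if rng is not None:
                    sigma = np.sqrt(2.0 * spec.diffusivity * spec.dt)
                    nx = nx + rng.normal(0.0, sigma, nx.size)
                    ny = ny + rng.normal(0.0, sigma, ny.size)
                in_box = (nx >= x0b) & (nx <= x1b) & (ny >= y0b) & (ny <= y1b)
                wet = _is_wet_many(field, np.where(in_box, nx, x0b), np.where(in_box, ny, y0b))
                ok = in_box & wet
                idx = np.flatnonzero(active)
                moved = idx[ok]
                x[moved] = nx[ok]
                y[moved] = ny[ok]
                cur_status[idx[~in_box]] = STATUS_OUT_OF_DOMAIN
                cur_status[idx[in_box & ~wet]] = STATUS_BEACHED
            t += spec.dt
        out[:, rec, 0] = x
        out[:, rec, 1] = y
        status[:, rec] = cur_status

    if station_xy is None:
        station_xy = (float(np.mean(positions[:, 0])), float(np.mean(positions[:, 1])))
    elapsed = np.arange(n_rec) * spec.record_interval
    return TrajectorySet(
        station_id=station_id,
        sample_time=t_start,
        elapsed=elapsed,
        positions=out,
        status=status,
        station_x=station_xy[0],
        station_y=station_xy[1],
    )


def backtrack(
    field: FlowField,
    station: Station,
    sample_time: float,
    spec: ReleaseSpec,
) -> TrajectorySet:
    """Backtrack a release from ``station`` arriving at ``sample_time``.

    Equivalent to forward advection through :func:`reverse_field`, starting
    at the reversed-time image of the sampling time.  The returned
    ``elapsed`` axis is seconds before sampling; the elapsed-0 record is the
    release disc itself, satisfying the arrival constraint that particles
    be at the station at the precise sampling time.
    """
    t0, t1 = field.time_span
    if sample_time - spec.duration < t0 - 1e-9 or sample_time > t1 + 1e-9:
        raise ConfigurationError(
            f"field time span [{t0}, {t1}] does not cover the backtracking "
            f"window [{sample_time - spec.duration}, {sample_time}]"
        )
    rev = reverse_field(field)
    start = release_positions(station, spec)
    # reversed-time image of the sampling instant (reversed axis anchored at 0)
    t_rev = field.times[-1] - sample_time
    traj = advect(rev, start, t_rev, spec, station_id=station.id, station_xy=(station.x, station.y))
    traj.sample_time = float(sample_time)
    return traj


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_stations(path) -> list[Station]:
    """Stations CSV: columns station_id, name (optional), x_m, y_m."""
    df = pd.read_csv(path)
    for col in ("station_id", "x_m", "y_m"):
        if col not in df.columns:
            raise TrackerError(f"stations file missing column '{col}'")
    return [Station(id=str(r.station_id), x=float(r.x_m), y=float(r.y_m)) for r in df.itertuples()]


def read_sampling_times(path, epoch: str | None = None) -> dict[str, list[float]]:
    """Sampling-times CSV: columns station_id, sample_time_iso.

    Times are converted to seconds since ``epoch`` (default: the earliest
    time in the file).
    """
    df = pd.read_csv(path)
    for col in ("station_id", "sample_time_iso"):
        if col not in df.columns:
            raise TrackerError(f"sampling-times file missing column '{col}'")
    ts = pd.to_datetime(df["sample_time_iso"])
    ref = pd.to_datetime(epoch) if epoch is not None else ts.min()
    df = df.assign(_sec=(ts - ref).dt.total_seconds())
    return {
        str(sid): sorted(g["_sec"].tolist()) for sid, g in df.groupby("station_id")
    }


def write_trajectories(traj: TrajectorySet, path) -> None:
    """Persist a TrajectorySet as netCDF (dims particle, record)."""
    ds = xr.Dataset(
        {
            "x": (("particle", "record"), traj.positions[:, :, 0].astype(np.float64), {"units": "m"}),
            "y": (("particle", "record"), traj.positions[:, :, 1].astype(np.float64), {"units": "m"}),
            "status": (("particle", "record"), traj.status.astype(np.int8),
                       {"flag_values": "0 1 2", "flag_meanings": "active beached out_of_domain"}),
        },
        coords={"elapsed": ("record", traj.elapsed, {"units": "s before sampling"})},
        attrs={
            "station_id": traj.station_id,
            "sample_time": traj.sample_time,
            "station_x": traj.station_x,
            "station_y": traj.station_y,
        },
    )
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def read_trajectories(path) -> TrajectorySet:
    with xr.open_dataset(path, engine="scipy") as ds:
        positions = np.stack([ds["x"].values, ds["y"].values], axis=-1)
        return TrajectorySet(
            station_id=str(ds.attrs["station_id"]),
            sample_time=float(ds.attrs["sample_time"]),
            elapsed=ds["elapsed"].values.astype(float),
            positions=positions.astype(float),
            status=ds["status"].values.astype(np.int8),
            station_x=float(ds.attrs["station_x"]),
            station_y=float(ds.attrs["station_y"]),
        )
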