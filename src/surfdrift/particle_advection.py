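"""Passive-particle advection through gridded surface currents.

Positions advance with a classical fourth-order Runge-Kutta scheme through a
velocity field interpolated bilinearly in space (among the four surrounding
valid grid cells, weights renormalised over valid cells) and linearly in time
between bracketing hourly maps.  Velocities are cm/s at I/O and converted
once to km/h internally (1 cm/s = 0.036 km/h).

Tracking follows the observation cadence: positions are logged every whole
hour and a particle exits at the first hourly log outside the data
footprint.  Sub-hour excursions out and back are not exits.  A particle with
no sampleable velocity for more than ``max_gap_hours`` consecutive hours
terminates with reason ``entered_persistent_gap`` and is counted as having
left the footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .velocity_field import CM_S_TO_KM_H, VelocityFieldSeries

EXIT_NONE = 0
EXIT_LEFT_FOOTPRINT = 1
EXIT_PERSISTENT_GAP = 2
EXIT_CENSORED = 3

EXIT_REASONS = {
    EXIT_NONE: "active",
    EXIT_LEFT_FOOTPRINT: "left_footprint",
    EXIT_PERSISTENT_GAP: "entered_persistent_gap",
    EXIT_CENSORED: "record_end",
}


@dataclass
class Trajectory:
    """One particle's hourly track."""

    particle_id: int
    release_xy: tuple[float, float]
    release_time: pd.Timestamp
    positions: np.ndarray  # (n_logged, 2) km, hourly from release
    exit_time_h: float | None  # hours since release; None if censored
    exit_reason: str

    @property
    def censored(self) -> bool:
        return self.exit_time_h is None


def _spatial_sample(field: VelocityFieldSeries, it: int, px: np.ndarray, py: np.ndarray):
    """Bilinear velocity (km/h) at one time index; weights renormalised over
    the valid neighbours.  Returns (u, v, valid)."""
    dom = field.domain
    dx = dom.spacing
    fx = (px - dom.origin[0]) / dx - 0.5
    fy = (py - dom.origin[1]) / dx - 0.5
    i0 = np.floor(fx).astype(int)
    j0 = np.floor(fy).astype(int)
    wx = fx - i0
    wy = fy - j0

    u = np.zeros_like(px)
    v = np.zeros_like(px)
    wsum = np.zeros_like(px)
    umap, vmap, mmap = field.u[it], field.v[it], field.mask[it]
    for di, dj, w in (
        (0, 0, (1 - wx) * (1 - wy)),
        (1, 0, wx * (1 - wy)),
        (0, 1, (1 - wx) * wy),
        (1, 1, wx * wy),
    ):
        i = i0 + di
        j = j0 + dj
        ok = (i >= 0) & (i < dom.nx) & (j >= 0) & (j < dom.ny)
        ii = np.clip(i, 0, dom.nx - 1)
        jj = np.clip(j, 0, dom.ny - 1)
        ok &= mmap[jj, ii]
        wv = np.where(ok, w, 0.0)
        u += wv * umap[jj, ii]
        v += wv * vmap[jj, ii]
        wsum += wv
    valid = wsum > 1e-12
    scale = np.where(valid, CM_S_TO_KM_H / np.where(valid, wsum, 1.0), 0.0)
    return u * scale, v * scale, valid


def sample_velocity(field: VelocityFieldSeries, positions: np.ndarray, t_hours: float):
    """Velocity (km/h) at positions (n, 2) and time `t_hours` past record
    start: bilinear in space, linear between bracketing hourly maps.  If only
    one bracketing hour has valid data the valid one is used; with none the
    particle is flagged invalid.  Raises if the time lies outside the record.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    cadence = field.dt_hours
    ft = t_hours / cadence
    if ft < -1e-9 or ft > field.nt - 1 + 1e-9:
        raise ValueError(f"time {t_hours} h outside the field record")
    it0 = int(np.clip(np.floor(ft), 0, field.nt - 1))
    alpha = float(ft - it0)
    px, py = positions[:, 0], positions[:, 1]
    u0, v0, ok0 = _spatial_sample(field, it0, px, py)
    if alpha <= 1e-12 or it0 == field.nt - 1:
        return np.column_stack([u0, v0]), ok0
    u1, v1, ok1 = _spatial_sample(field, it0 + 1, px, py)
    both = ok0 & ok1
    u = np.where(both, (1 - alpha) * u0 + alpha * u1, np.where(ok0, u0, u1))
    v = np.where(both, (1 - alpha) * v0 + alpha * v1, np.where(ok0, v0, v1))
    return np.column_stack([u, v]), ok0 | ok1


def rk4_step(field: VelocityFieldSeries, positions: np.ndarray, t_hours: float, dt: float):
    """Classical RK4 position update over `dt` hours.

    Returns (new_positions, ok): particles for which any stage velocity is
    unsampleable keep their position and come back with ok = False (the
    caller treats this as a data-gap signal).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pos = np.atleast_2d(np.asarray(positions, float))
    k1, ok = sample_velocity(field, pos, t_hours)
    k2, o2 = sample_velocity(field, pos + 0.5 * dt * k1, t_hours + 0.5 * dt)
    k3, o3 = sample_velocity(field, pos + 0.5 * dt * k2, t_hours + 0.5 * dt)
    k4, o4 = sample_velocity(field, pos + dt * k3, t_hours + dt)
    ok = ok & o2 & o3 & o4
    new = pos + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return np.where(ok[:, None], new, pos), ok


try:  # fast per-hour kernel; the numpy path below is the reference
    from numba import njit

    @njit(cache=False, inline="always")
    def _sample_nb(u, v, m, ox, oy, dx, nx, ny, x, y):
        fx = (x - ox) / dx - 0.5
        fy = (y - oy) / dx - 0.5
        i0 = int(np.floor(fx))
        j0 = int(np.floor(fy))
        wx = fx - i0
        wy = fy - j0
        us = 0.0
        vs = 0.0
        ws = 0.0
        for di in range(2):
            for dj in range(2):
                i = i0 + di
                j = j0 + dj
                if 0 <= i < nx and 0 <= j < ny and m[j, i]:
                    w = (wx if di == 1 else 1.0 - wx) * (wy if dj == 1 else 1.0 - wy)
                    us += w * u[j, i]
                    vs += w * v[j, i]
                    ws += w
        if ws > 1e-12:
            return us / ws, vs / ws, True
        return 0.0, 0.0, False

    @njit(cache=False, inline="always")
    def _vel_nb(u0, v0, m0, u1, v1, m1, ox, oy, dx, nx, ny, x, y, alpha, conv):
        # at an exact map time only that map participates (matches the
        # reference sample_velocity path)
        if alpha <= 1e-12:
            ua, va, oka = _sample_nb(u0, v0, m0, ox, oy, dx, nx, ny, x, y)
            return ua * conv, va * conv, oka
        if alpha >= 1.0 - 1e-12:
            ub, vb, okb = _sample_nb(u1, v1, m1, ox, oy, dx, nx, ny, x, y)
            return ub * conv, vb * conv, okb
        ua, va, oka = _sample_nb(u0, v0, m0, ox, oy, dx, nx, ny, x, y)
        ub, vb, okb = _sample_nb(u1, v1, m1, ox, oy, dx, nx, ny, x, y)
        if oka and okb:
            return (
                ((1.0 - alpha) * ua + alpha * ub) * conv,
                ((1.0 - alpha) * va + alpha * vb) * conv,
                True,
            )
        if oka:
            return ua * conv, va * conv, True
        if okb:
            return ub * conv, vb * conv, True
        return 0.0, 0.0, False

    @njit(cache=False)
    def _advect_hour_nb(u0, v0, m0, u1, v1, m1, ox, oy, dx, nx, ny, pos, nsub, conv):
        n = pos.shape[0]
        ok_out = np.ones(n, np.bool_)
        h = 1.0 / nsub
        for p in range(n):
            x = pos[p, 0]
            y = pos[p, 1]
            for s in range(nsub):
                a = s * h
                k1u, k1v, o1 = _vel_nb(u0, v0, m0, u1, v1, m1, ox, oy, dx, nx, ny, x, y, a, conv)
                k2u, k2v, o2 = _vel_nb(
                    u0, v0, m0, u1, v1, m1, ox, oy, dx, nx, ny,
                    x + 0.5 * h * k1u, y + 0.5 * h * k1v, a + 0.5 * h, conv,
                )
                k3u, k3v, o3 = _vel_nb(
                    u0, v0, m0, u1, v1, m1, ox, oy, dx, nx, ny,
                    x + 0.5 * h * k2u, y + 0.5 * h * k2v, a + 0.5 * h, conv,
                )
                k4u, k4v, o4 = _vel_nb(
                    u0, v0, m0, u1, v1, m1, ox, oy, dx, nx, ny,
                    x + h * k3u, y + h * k3v, a + h, conv,
                )
                if o1 and o2 and o3 and o4:
                    x += (h / 6.0) * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
                    y += (h / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
                else:
                    ok_out[p] = False
                    break  # frozen for the rest of the hour
            pos[p, 0] = x
            pos[p, 1] = y
        return ok_out

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in practice
    HAVE_NUMBA = False


def track_batch(
    field: VelocityFieldSeries,
    releases: np.ndarray,
    release_time,
    dt: float = 0.1,
    horizon_h: float = 240.0,
    max_gap_hours: int = 3,
    stop_after_exits: int | None = None,
    log_positions: bool = True,
    use_fast_kernel: bool = True,
):
    """Advect a batch of particles released together; hourly logging.

    Returns a dict with ``positions`` (n_hours+1, n, 2; NaN after exit, and
    None when ``log_positions`` is False), ``exit_time_h`` (NaN = censored),
    ``exit_code`` and ``n_hours``.  ``stop_after_exits`` ends the hourly loop
    once that many particles have exited (the rest are censored), which is
    enough for residence-time work.
    """
    dom = field.domain
    releases = np.atleast_2d(np.asarray(releases, float))
    n = len(releases)
    inside = dom.in_footprint_many(releases)
    if not inside.all():
        bad = np.where(~inside)[0]
        raise ValueError(f"release positions outside footprint: indices {bad.tolist()}")
    t0 = field.time_offset_hours(release_time)
    if t0 < -1e-9 or t0 > (field.nt - 1) * field.dt_hours + 1e-9:
        raise ValueError("release time outside the field record")
    nh = int(min(horizon_h, (field.nt - 1) * field.dt_hours - t0))
    nsub = max(int(round(1.0 / dt)), 1)
    dt_eff = 1.0 / nsub

    pos = releases.copy()
    logged = np.full((nh + 1, n, 2), np.nan) if log_positions else None
    if log_positions:
        logged[0] = pos
    exit_time = np.full(n, np.nan)
    exit_code = np.full(n, EXIT_NONE, dtype=int)
    gap_hours = np.zeros(n, dtype=int)
    active = np.ones(n, bool)

    fast = (
        use_fast_kernel
        and HAVE_NUMBA
        and field.dt_hours == 1.0
        and abs(t0 - round(t0)) < 1e-9
    )
    dom_args = (
        dom.origin[0],
        dom.origin[1],
        dom.spacing,
        dom.nx,
        dom.ny,
    )
    for h in range(nh):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        p = pos[idx]
        t = t0 + h
        if fast:
            it = int(round(t))
            p = np.ascontiguousarray(p)
            moved_ok = _advect_hour_nb(
                field.u[it],
                field.v[it],
                field.mask[it],
                field.u[it + 1],
                field.v[it + 1],
                field.mask[it + 1],
                *dom_args,
                p,
                nsub,
                CM_S_TO_KM_H,
            )
        else:
            moved_ok = np.ones(idx.size, bool)
            for s in range(nsub):
                p_new, ok = rk4_step(field, p, t + s * dt_eff, dt_eff)
                # particles hitting a gap freeze for the rest of this hour
                moved_ok &= ok
                p = np.where(moved_ok[:, None], p_new, p)
        pos[idx] = p
        gap_hours[idx] = np.where(moved_ok, 0, gap_hours[idx] + 1)

        now_h = h + 1
        if log_positions:
            logged[now_h, idx] = p
        outside = ~dom.in_footprint_many(p)
        gap_exit = gap_hours[idx] > max_gap_hours
        left = idx[outside]
        gapped = idx[gap_exit & ~outside]
        exit_time[left] = now_h
        exit_code[left] = EXIT_LEFT_FOOTPRINT
        exit_time[gapped] = now_h
        exit_code[gapped] = EXIT_PERSISTENT_GAP
        active[left] = False
        active[gapped] = False
        if stop_after_exits is not None and (~active).sum() >= stop_after_exits:
            break

    exit_code[active] = EXIT_CENSORED
    return {
        "positions": logged,
        "exit_time_h": exit_time,
        "exit_code": exit_code,
        "n_hours": nh,
        "release_time": pd.Timestamp(release_time),
    }


def track(
    field: VelocityFieldSeries,
    release_xy,
    release_time,
    dt: float = 0.1,
    horizon_h: float = 240.0,
    particle_id: int = 0,
    max_gap_hours: int = 3,
) -> Trajectory:
    """Track a single particle; see `track_batch`."""
    res = track_batch(
        field,
        np.asarray([release_xy], float),
        release_time,
        dt=dt,
        horizon_h=horizon_h,
        max_gap_hours=max_gap_hours,
    )
    et = res["exit_time_h"][0]
    code = res["exit_code"][0]
    npos = res["n_hours"] + 1 if np.isnan(et) else int(et) + 1
    return Trajectory(
        particle_id=particle_id,
        release_xy=tuple(np.asarray(release_xy, float)),
        release_time=pd.Timestamp(release_time),
        positions=res["positions"][:npos, 0, :],
        exit_time_h=None if np.isnan(et) else float(et),
        exit_reason=EXIT_REASONS[code],
    )


def tracks_to_csv(batch: dict, domain, path: str, release_id: str = "") -> None:
    """Long-form per-hour track CSV (particle_id, time, x_km, y_km, lon, lat)."""
    logged = batch["positions"]
    rows = []
    t0 = batch["release_time"]
    for h in range(logged.shape[0]):
        for pid in range(logged.shape[1]):
            x, y = logged[h, pid]
            if np.isnan(x):
                continue
            lon, lat = domain.km_to_lonlat(x, y)
            rows.append((release_id, pid, t0 + pd.Timedelta(hours=h), x, y, float(lon), float(lat)))
    pd.DataFrame(
        rows, columns=["release", "particle_id", "time", "x_km", "y_km", "lon", "lat"]
    ).to_csv(path, index=False)
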