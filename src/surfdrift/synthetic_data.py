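"""Synthetic HFR-like surface currents and two-station winds.

Generates hourly total-vector current maps and 15-minute wind series with the
statistical structure the downstream analysis assumes: a persistent eastward
coastal current, diurnal/semi-diurnal tidal harmonics (O1, K1, M2, S2), a
wind-coupled surface component, a non-divergent mesoscale eddy field built
from a random-Fourier-mode streamfunction with AR(1) temporal evolution, and
random coverage gaps (default 3%, i.e. 97% average coverage).

All randomness flows from one seed; identical configs give bitwise-identical
output.  Winds at the two stations are noisy observations of a shared latent
wind, and the same latent wind drives the wind-coupled current component, so
the wind->current coupling survives into the merged station average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .domain_geometry import DomainSpec
from .velocity_field import VelocityFieldSeries

#: Darwin constituent periods (hours); no nodal corrections.
CONSTITUENT_PERIODS_H = {
    "M2": 12.4206012,
    "S2": 12.0,
    "K1": 23.9344697,
    "O1": 25.8193417,
}


def constituent_frequencies(names) -> dict[str, float]:
    """Angular frequencies (rad/h) for named constituents."""
    out = {}
    for n in names:
        if n not in CONSTITUENT_PERIODS_H:
            raise KeyError(f"unknown tidal constituent {n!r}")
        out[n] = 2.0 * np.pi / CONSTITUENT_PERIODS_H[n]
    return out


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic-data generator.

    Tidal amplitudes are (u, v) pairs in cm/s per constituent; phases in
    degrees.  ``tidal_variance_fraction``, if set, rescales all tidal
    amplitudes so the tidal share of total velocity variance over the record
    hits the given fraction (the field's observed value is about 0.123).
    ``wind_coupling`` is the fraction of the wind speed appearing as surface
    current, directed downwind plus ``wind_deflection_deg`` (positive =
    clockwise).
    """

    start: str = "2015-01-01T00:00"
    duration_days: float = 60.0
    mean_current_cms: tuple[float, float] = (12.0, 0.0)  # eastward coastal current
    tidal_amplitudes: dict = field(
        default_factory=lambda: {
            "M2": (6.0, 4.0),
            "S2": (3.0, 2.0),
            "K1": (4.0, 2.5),
            "O1": (3.0, 2.0),
        }
    )
    tidal_phases_deg: dict = field(
        default_factory=lambda: {"M2": (0.0, 90.0), "S2": (30.0, 120.0), "K1": (60.0, 150.0), "O1": (45.0, 135.0)}
    )
    tidal_variance_fraction: float | None = None
    wind_coupling: float = 0.03
    wind_deflection_deg: float = 0.0
    eddy_rms_cms: float = 6.0
    eddy_length_km: float = 12.0
    eddy_timescale_h: float = 36.0
    eddy_n_modes: int = 8
    gap_fraction: float = 0.03
    wind_mean_ms: float = 6.0
    wind_sd_ms: float = 2.5
    wind_timescale_h: float = 36.0
    wind_direction_mean_deg: float = 30.0
    wind_direction_walk_deg: float = 8.0  # per 15-min step
    station_noise_ms: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must lie in [0, 1)")
        if self.wind_mean_ms < 0:
            raise ValueError("mean wind speed must be non-negative")
        for name, (au, av) in self.tidal_amplitudes.items():
            if au < 0 or av < 0:
                raise ValueError(f"negative tidal amplitude for {name}")


@dataclass(frozen=True)
class WindSeries:
    """15-minute wind observations at one station.

    ``direction_deg`` is the direction the wind blows FROM, degrees clockwise
    from true north (meteorological convention).
    """

    station: str
    times: pd.DatetimeIndex
    speed_ms: np.ndarray
    direction_deg: np.ndarray

    def __post_init__(self):
        if (self.speed_ms < 0).any():
            raise ValueError("wind speed must be non-negative")
        d = np.asarray(self.direction_deg)
        ok = np.isnan(d) | ((d >= 0) & (d < 360))
        if not ok.all():
            raise ValueError("direction must lie in [0, 360) or be NaN")
        if len(self.times) > 1 and not (np.diff(self.times.values) > np.timedelta64(0)).all():
            raise ValueError("timestamps must strictly increase")

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"time": self.times, "speed_ms": self.speed_ms, "direction_deg": self.direction_deg}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, station: str = "") -> "WindSeries":
        df = pd.read_csv(path, parse_dates=["time"])
        return cls(
            station=station,
            times=pd.DatetimeIndex(df["time"]),
            speed_ms=df["speed_ms"].to_numpy(float),
            direction_deg=df["direction_deg"].to_numpy(float),
        )


# -- latent wind (shared by currents and station observations) -------------


def _latent_wind(config: SynthConfig):
    """15-min latent wind: AR(1) red-noise speed, random-walk direction."""
    rng = np.random.default_rng([config.seed, 101])
    n = int(round(config.duration_days * 96)) + 1
    times = pd.date_range(config.start, periods=n, freq="15min")
    rho = np.exp(-0.25 / config.wind_timescale_h)  # 15-min step
    eps = rng.standard_normal(n)
    dev = np.empty(n)
    dev[0] = eps[0]
    for k in range(1, n):
        dev[k] = rho * dev[k - 1] + np.sqrt(1 - rho**2) * eps[k]
    speed = np.clip(config.wind_mean_ms + config.wind_sd_ms * dev, 0.0, None)
    steps = rng.standard_normal(n) * config.wind_direction_walk_deg
    direction = np.mod(config.wind_direction_mean_deg + np.cumsum(steps) - steps[0], 360.0)
    return times, speed, direction


def wind_to_current_cms(speed_ms, direction_from_deg, coupling, deflection_deg=0.0):
    """Surface-current vector (cm/s) driven by a wind blowing FROM the given
    direction: magnitude coupling * speed, directed downwind rotated by the
    deflection angle (positive clockwise)."""
    to_deg = np.deg2rad(np.mod(np.asarray(direction_from_deg) + 180.0 + deflection_deg, 360.0))
    mag = coupling * np.asarray(speed_ms) * 100.0  # m/s -> cm/s
    u = mag * np.sin(to_deg)
    v = mag * np.cos(to_deg)
    return u, v


# -- currents --------------------------------------------------------------


def _eddy_field(config: SynthConfig, domain: DomainSpec, times: pd.DatetimeIndex, rng):
    """Non-divergent eddy velocity from a random Fourier streamfunction.

    psi(x, y, t) = sum_m A_m(t) sin(kx_m x + ky_m y + phi_m); u = -dpsi/dy,
    v = dpsi/dx evaluated analytically, so the continuum field is exactly
    divergence-free and the discrete divergence is small for wavelengths well
    above the grid spacing.
    """
    nm = config.eddy_n_modes
    if nm == 0 or config.eddy_rms_cms == 0:
        z = np.zeros((len(times), domain.ny, domain.nx))
        return z, z.copy()
    k0 = 2 * np.pi / config.eddy_length_km
    kmag = k0 * rng.uniform(0.7, 1.3, nm)
    kang = rng.uniform(0, 2 * np.pi, nm)
    kx, ky = kmag * np.cos(kang), kmag * np.sin(kang)
    phi = rng.uniform(0, 2 * np.pi, nm)

    x = domain.origin[0] + (np.arange(domain.nx) + 0.5) * domain.spacing
    y = domain.origin[1] + (np.arange(domain.ny) + 0.5) * domain.spacing
    gx, gy = np.meshgrid(x, y)
    arg = kx[:, None, None] * gx + ky[:, None, None] * gy + phi[:, None, None]
    cos_m = np.cos(arg)  # (nm, ny, nx)

    nt = len(times)
    rho = np.exp(-1.0 / config.eddy_timescale_h)  # hourly step
    amp = np.empty((nt, nm))
    amp[0] = rng.standard_normal(nm)
    innov = rng.standard_normal((nt, nm))
    for k in range(1, nt):
        amp[k] = rho * amp[k - 1] + np.sqrt(1 - rho**2) * innov[k]

    u = -np.einsum("tm,mYX->tYX", amp * ky, cos_m)
    v = np.einsum("tm,mYX->tYX", amp * kx, cos_m)
    rms = np.sqrt(np.mean(u**2 + v**2))
    if rms > 0:
        scale = config.eddy_rms_cms / rms
        u *= scale
        v *= scale
    return u, v


def _tidal_series(config: SynthConfig, t_hours: np.ndarray):
    """Tidal (u, v) harmonic sums (cm/s) at the given hour offsets."""
    u = np.zeros_like(t_hours, dtype=float)
    v = np.zeros_like(t_hours, dtype=float)
    freqs = constituent_frequencies(config.tidal_amplitudes.keys())
    for name, (au, av) in config.tidal_amplitudes.items():
        pu, pv = config.tidal_phases_deg.get(name, (0.0, 0.0))
        w = freqs[name]
        u += au * np.cos(w * t_hours - np.deg2rad(pu))
        v += av * np.cos(w * t_hours - np.deg2rad(pv))
    return u, v


def synth_currents(config: SynthConfig, domain: DomainSpec) -> VelocityFieldSeries:
    """Hourly u, v grids: mean current + tidal harmonics + wind-coupled
    component + eddy field, with a random coverage mask."""
    slowest = max(
        (CONSTITUENT_PERIODS_H[n] for n in config.tidal_amplitudes), default=0.0
    )
    if config.tidal_amplitudes and config.duration_days * 24 < 2 * slowest:
        warnings.warn(
            "record shorter than two periods of the slowest constituent; "
            "a downstream tidal fit will be ill-conditioned",
            stacklevel=2,
        )
    nt = int(round(config.duration_days * 24)) + 1
    times = pd.date_range(config.start, periods=nt, freq="1h")
    t_hours = np.arange(nt, dtype=float)

    tide_u, tide_v = _tidal_series(config, t_hours)

    wt, wspeed, wdir = _latent_wind(config)
    # hourly samples of the latent 15-min wind
    wind_u, wind_v = wind_to_current_cms(
        wspeed[::4][:nt], wdir[::4][:nt], config.wind_coupling, config.wind_deflection_deg
    )

    rng = np.random.default_rng([config.seed, 202])
    eddy_u, eddy_v = _eddy_field(config, domain, times, rng)

    base_u = config.mean_current_cms[0] + wind_u[:, None, None] + eddy_u
    base_v = config.mean_current_cms[1] + wind_v[:, None, None] + eddy_v

    scale = 1.0
    if config.tidal_variance_fraction is not None:
        f = config.tidal_variance_fraction
        var_nt = np.mean(
            (base_u - base_u.mean(axis=0)) ** 2 + (base_v - base_v.mean(axis=0)) ** 2
        )
        var_t = np.mean((tide_u - tide_u.mean()) ** 2 + (tide_v - tide_v.mean()) ** 2)
        if var_t > 0:
            scale = np.sqrt(f / (1.0 - f) * var_nt / var_t)

    u = base_u + scale * tide_u[:, None, None]
    v = base_v + scale * tide_v[:, None, None]

    gap_rng = np.random.default_rng([config.seed, 303])
    mask = gap_rng.random((nt, domain.ny, domain.nx)) >= config.gap_fraction
    mask &= domain.footprint[None, :, :]

    return VelocityFieldSeries(times=times, u=u, v=v, mask=mask, domain=domain)


# -- winds -----------------------------------------------------------------


def synth_winds(config: SynthConfig) -> tuple[WindSeries, WindSeries]:
    """Two correlated station wind series observing the shared latent wind."""
    times, speed, direction = _latent_wind(config)
    out = []
    for k, station in enumerate(("JOU", "WAU")):
        rng = np.random.default_rng([config.seed, 404 + k])
        n = len(times)
        rho = np.exp(-0.25 / 6.0)  # 6 h station-noise decorrelation
        eps = rng.standard_normal(n)
        dev = np.empty(n)
        dev[0] = eps[0]
        for i in range(1, n):
            dev[i] = rho * dev[i - 1] + np.sqrt(1 - rho**2) * eps[i]
        sp = np.clip(speed + config.station_noise_ms * dev, 0.0, None)
        if config.station_noise_ms > 0:
            ddev = rng.standard_normal(n) * 5.0
        else:
            ddev = np.zeros(n)
        dr = np.mod(direction + ddev, 360.0)
        out.append(
            WindSeries(station=station, times=times, speed_ms=sp, direction_deg=dr)
        )
    return out[0], out[1]


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    return replace(config, seed=int(seed))
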