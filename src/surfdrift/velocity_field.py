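"""Hourly gridded surface-velocity series: the substrate for de-tiding and
particle advection.

Velocities are stored in cm/s on the domain's 1 km grid with a per-cell-hour
coverage mask (True = valid observation).  NetCDF round-trips use xarray with
CF-style variable names for eastward/northward surface velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .domain_geometry import DomainSpec, build_domain

#: 1 cm/s expressed in km/h; applied once when velocities enter the integrator.
CM_S_TO_KM_H = 0.036


@dataclass
class VelocityFieldSeries:
    """Hourly u, v component grids (cm/s) with coverage mask.

    Arrays are shaped (nt, ny, nx); ``times`` is a pandas DatetimeIndex at
    uniform hourly cadence.  ``mask`` is True where the cell-hour holds a
    valid observation.
    """

    times: pd.DatetimeIndex
    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    domain: DomainSpec

    def __post_init__(self):
        nt = len(self.times)
        for name, arr in (("u", self.u), ("v", self.v), ("mask", self.mask)):
            if arr.shape != (nt, self.domain.ny, self.domain.nx):
                raise ValueError(f"{name} shape {arr.shape} inconsistent with grid")
        if nt > 1:
            steps = np.diff(self.times.values)
            if not (steps == steps[0]).all():
                raise ValueError("timestamps must be uniform")
        if not np.isfinite(self.u[self.mask]).all() or not np.isfinite(
            self.v[self.mask]
        ).all():
            raise ValueError("non-finite velocity under valid mask")

    @property
    def nt(self) -> int:
        return len(self.times)

    @property
    def dt_hours(self) -> float:
        if self.nt < 2:
            return 1.0
        return float((self.times[1] - self.times[0]) / pd.Timedelta(hours=1))

    def time_offset_hours(self, when) -> float:
        """Hours of `when` past the start of the record."""
        return float((pd.Timestamp(when) - self.times[0]) / pd.Timedelta(hours=1))

    def subwindow(self, start, end) -> "VelocityFieldSeries":
        sel = (self.times >= pd.Timestamp(start)) & (self.times <= pd.Timestamp(end))
        return VelocityFieldSeries(
            times=self.times[sel],
            u=self.u[sel],
            v=self.v[sel],
            mask=self.mask[sel],
            domain=self.domain,
        )

    # -- I/O ---------------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        x = self.domain.origin[0] + (np.arange(self.domain.nx) + 0.5) * self.domain.spacing
        y = self.domain.origin[1] + (np.arange(self.domain.ny) + 0.5) * self.domain.spacing
        ds = xr.Dataset(
            {
                "eastward_sea_water_velocity": (
                    ("time", "y", "x"),
                    np.where(self.mask, self.u, np.nan).astype("f4"),
                    {"units": "cm s-1"},
                ),
                "northward_sea_water_velocity": (
                    ("time", "y", "x"),
                    np.where(self.mask, self.v, np.nan).astype("f4"),
                    {"units": "cm s-1"},
                ),
                "coverage": (("time", "y", "x"), self.mask.astype("i1")),
            },
            coords={"time": self.times, "x": ("x", x, {"units": "km"}), "y": ("y", y, {"units": "km"})},
            attrs={
                "anchor_lon": self.domain.anchor_lonlat[0],
                "anchor_lat": self.domain.anchor_lonlat[1],
            },
        )
        return ds

    def to_netcdf(self, path: str) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    def to_long_csv(self, path: str) -> None:
        """Long-form (time, x, y, u, v, mask) CSV; large for big grids."""
        ds = self.to_dataset()
        df = ds.to_dataframe().reset_index()
        df.to_csv(path, index=False)

    @classmethod
    def from_netcdf(cls, path: str, domain: DomainSpec) -> "VelocityFieldSeries":
        ds = xr.open_dataset(path, engine="scipy")
        mask = ds["coverage"].values.astype(bool)
        u = np.nan_to_num(ds["eastward_sea_water_velocity"].values.astype(float))
        v = np.nan_to_num(ds["northward_sea_water_velocity"].values.astype(float))
        return cls(
            times=pd.DatetimeIndex(ds["time"].values), u=u, v=v, mask=mask, domain=domain
        )
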