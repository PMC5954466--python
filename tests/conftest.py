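import numpy as np
import pandas as pd
import pytest

from surfdrift.domain_geometry import build_domain
from surfdrift.velocity_field import VelocityFieldSeries

#: Scaled-down study domain used by the heavier pipeline tests: 20 x 20 km
#: footprint with canyon/flank sub-regions holding 32/18/18 release points.
SMALL_CONFIG = {
    "nx": 20,
    "ny": 20,
    "spacing": 1.0,
    "origin": (0.0, 0.0),
    "anchor_lonlat": (-64.4, -64.9),
    "target_area_km2": 400.0,
    "subregions": {
        "CAN": [(8, 6), (12, 6), (12, 14), (8, 14)],
        "JIF": [(3, 7), (6, 7), (6, 13), (3, 13)],
        "WIF": [(14, 7), (17, 7), (17, 13), (14, 13)],
    },
}

#: 5 x 5 km toy domain for brute-force oracle checks: three side-by-side
#: regions and a uniform eastward flow make every exit time hand-computable.
TOY_CONFIG = {
    "nx": 5,
    "ny": 5,
    "spacing": 1.0,
    "origin": (0.0, 0.0),
    "anchor_lonlat": (-64.4, -64.9),
    "target_area_km2": 25.0,
    "subregions": {
        "JIF": [(0, 1), (1, 1), (1, 4), (0, 4)],
        "CAN": [(1, 1), (3, 1), (3, 4), (1, 4)],
        "WIF": [(3, 1), (5, 1), (5, 4), (3, 4)],
    },
}


@pytest.fixture(scope="session")
def demo_domain():
    return build_domain()


@pytest.fixture(scope="session")
def small_domain():
    return build_domain(SMALL_CONFIG)


@pytest.fixture(scope="session")
def toy_domain():
    return build_domain(TOY_CONFIG)


def make_uniform_field(domain, u_cms, v_cms, n_hours=72, start="2015-01-01"):
    times = pd.date_range(start, periods=n_hours + 1, freq="1h")
    shape = (len(times), domain.ny, domain.nx)
    return VelocityFieldSeries(
        times=times,
        u=np.full(shape, float(u_cms)),
        v=np.full(shape, float(v_cms)),
        mask=np.ones(shape, bool),
        domain=domain,
    )


def make_rotation_field(domain, period_h=12.0, center=None, n_hours=72):
    """Solid-body rotation (linear in x, y, so bilinear sampling is exact)."""
    if center is None:
        x0, x1, y0, y1 = domain.extent
        center = (0.5 * (x0 + x1), 0.5 * (y0 + y1))
    omega = 2.0 * np.pi / period_h  # rad/h
    x = domain.origin[0] + (np.arange(domain.nx) + 0.5) * domain.spacing
    y = domain.origin[1] + (np.arange(domain.ny) + 0.5) * domain.spacing
    gx, gy = np.meshgrid(x, y)
    u = -omega * (gy - center[1]) / 0.036  # km/h -> cm/s
    v = omega * (gx - center[0]) / 0.036
    times = pd.date_range("2015-01-01", periods=n_hours + 1, freq="1h")
    nt = len(times)
    return VelocityFieldSeries(
        times=times,
        u=np.repeat(u[None], nt, axis=0),
        v=np.repeat(v[None], nt, axis=0),
        mask=np.ones((nt, domain.ny, domain.nx), bool),
        domain=domain,
    )
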