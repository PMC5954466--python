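"""Analysis footprint, release grid and sub-region polygons.

The analysis lives on a local tangent-plane Cartesian grid (km), anchored to
a geographic origin with an equirectangular projection about the domain
centre; longitude/latitude appear only at I/O boundaries.  Release points sit
at the centres of 1 km cells.  Three named sub-regions — the central canyon
(CAN) and the Joubin (JIF) and Wauwermans (WIF) island flanks — partition the
release points; membership ties on shared polygon edges are broken by the
fixed ordering CAN -> JIF -> WIF.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon, shape
from shapely.prepared import prep

EARTH_RADIUS_KM = 6371.0

#: Fixed tie-break ordering for sub-region membership.
REGION_ORDER = ("CAN", "JIF", "WIF")


@dataclass(frozen=True)
class SubRegion:
    """A named sub-region polygon with the release points it owns."""

    name: str
    polygon: Polygon
    release_points: np.ndarray  # (n, 2) km coordinates

    @property
    def n_release(self) -> int:
        return len(self.release_points)


@dataclass(frozen=True)
class DomainSpec:
    """Footprint mask, release grid and sub-regions on a fixed 1 km grid.

    Cell (i, j) spans ``[origin + (i, j), origin + (i+1, j+1)]`` km with its
    centre at ``origin + (i + 0.5, j + 0.5)``; ``footprint[j, i]`` flags data
    coverage (row-major y, x like the velocity grids).
    """

    origin: tuple[float, float]
    nx: int
    ny: int
    spacing: float
    footprint: np.ndarray  # (ny, nx) bool
    subregions: tuple[SubRegion, ...]
    anchor_lonlat: tuple[float, float]
    target_area_km2: float = 1500.0
    _prepared: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if not self.footprint.any():
            raise ValueError("footprint is empty: no valid cells")
        area = self.footprint.sum() * self.spacing**2
        if abs(area - self.target_area_km2) > 0.2 * self.target_area_km2:
            raise ValueError(
                f"footprint area {area:.0f} km2 deviates more than 20% from "
                f"target {self.target_area_km2:.0f} km2"
            )
        for reg in self.subregions:
            if not reg.polygon.is_simple:
                raise ValueError(f"sub-region {reg.name} polygon self-intersects")
        for a in range(len(self.subregions)):
            for b in range(a + 1, len(self.subregions)):
                inter = self.subregions[a].polygon.intersection(
                    self.subregions[b].polygon
                )
                if inter.area > 1e-9:
                    raise ValueError(
                        f"sub-regions {self.subregions[a].name} and "
                        f"{self.subregions[b].name} overlap"
                    )
        object.__setattr__(
            self, "_prepared", tuple(prep(r.polygon) for r in self.subregions)
        )

    @property
    def area_km2(self) -> float:
        return float(self.footprint.sum()) * self.spacing**2

    @property
    def n_release_total(self) -> int:
        return sum(r.n_release for r in self.subregions)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) of the grid in km."""
        x0, y0 = self.origin
        return (x0, x0 + self.nx * self.spacing, y0, y0 + self.ny * self.spacing)

    # -- queries -----------------------------------------------------------

    def cell_index(self, x: float, y: float) -> tuple[int, int] | None:
        """Grid cell (i, j) containing the point, or None if off-grid."""
        i = math.floor((x - self.origin[0]) / self.spacing)
        j = math.floor((y - self.origin[1]) / self.spacing)
        if 0 <= i < self.nx and 0 <= j < self.ny:
            return i, j
        return None

    def in_footprint(self, x: float, y: float) -> bool:
        idx = self.cell_index(x, y)
        if idx is None:
            return False
        i, j = idx
        return bool(self.footprint[j, i])

    def locate(self, x: float, y: float) -> tuple[bool, str | None]:
        """Membership of a point: (in_footprint, sub-region name or None).

        Polygon membership uses the even-odd rule with boundary points
        counting as inside; ties resolved by REGION_ORDER, so the result is
        deterministic regardless of polygon construction order.
        """
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError("point coordinates must be finite")
        inside = self.in_footprint(x, y)
        pt = Point(x, y)
        by_name = {r.name: (r, p) for r, p in zip(self.subregions, self._prepared)}
        for name in REGION_ORDER:
            if name not in by_name:
                continue
            reg, prepared = by_name[name]
            # prepared.intersects includes the boundary
            if prepared.intersects(pt):
                return inside, name
        for reg, prepared in zip(self.subregions, self._prepared):
            if reg.name not in REGION_ORDER and prepared.intersects(pt):
                return inside, reg.name
        return inside, None

    def locate_many(self, xy: np.ndarray, region: str) -> np.ndarray:
        """Vectorised membership of points in one named sub-region."""
        reg = next(r for r in self.subregions if r.name == region)
        from shapely import contains_xy

        # covers boundary points too
        xy = np.asarray(xy, float)
        return contains_xy(reg.polygon.buffer(1e-9), xy[:, 0], xy[:, 1])

    def in_footprint_many(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        i = np.floor((xy[:, 0] - self.origin[0]) / self.spacing).astype(int)
        j = np.floor((xy[:, 1] - self.origin[1]) / self.spacing).astype(int)
        ok = (i >= 0) & (i < self.nx) & (j >= 0) & (j < self.ny)
        out = np.zeros(len(xy), bool)
        out[ok] = self.footprint[j[ok], i[ok]]
        return out

    # -- geographic conversion --------------------------------------------

    def km_to_lonlat(self, x, y):
        lon0, lat0 = self.anchor_lonlat
        lat = lat0 + np.asarray(y) / (EARTH_RADIUS_KM * math.pi / 180.0)
        lon = lon0 + np.asarray(x) / (
            EARTH_RADIUS_KM * math.pi / 180.0 * math.cos(math.radians(lat0))
        )
        return lon, lat

    def lonlat_to_km(self, lon, lat):
        lon0, lat0 = self.anchor_lonlat
        y = (np.asarray(lat) - lat0) * EARTH_RADIUS_KM * math.pi / 180.0
        x = (
            (np.asarray(lon) - lon0)
            * EARTH_RADIUS_KM
            * math.pi
            / 180.0
            * math.cos(math.radians(lat0))
        )
        return x, y


# -- construction ----------------------------------------------------------

#: Demo geometry: a 50 x 30 km footprint (1500 cells of 1 km^2) with a
#: central canyon rectangle flanked by two island-flank polygons whose
#: 1 km release grids hold 187 (CAN), 84 (JIF) and 61 (WIF) points.
DEMO_CONFIG = {
    "nx": 50,
    "ny": 30,
    "spacing": 1.0,
    "origin": (0.0, 0.0),
    "anchor_lonlat": (-64.4, -64.9),
    "target_area_km2": 1500.0,
    "subregions": {
        # CAN: 11 x 17 cells = 187 release points
        "CAN": [(20, 7), (31, 7), (31, 24), (20, 24)],
        # JIF: 7 x 12 cells = 84 release points
        "JIF": [(10, 10), (17, 10), (17, 22), (10, 22)],
        # WIF: L-shape, 7x1 + 6x9 cells = 61 release points
        "WIF": [(34, 10), (41, 10), (41, 11), (40, 11), (40, 20), (34, 20)],
    },
}


def _release_points_in(polygon: Polygon, domain_cfg: dict) -> np.ndarray:
    """Release-grid points (1 km cell centres) covered by a polygon."""
    nx, ny = domain_cfg["nx"], domain_cfg["ny"]
    dx = domain_cfg["spacing"]
    ox, oy = domain_cfg["origin"]
    xs = ox + (np.arange(nx) + 0.5) * dx
    ys = oy + (np.arange(ny) + 0.5) * dx
    gx, gy = np.meshgrid(xs, ys)
    from shapely import contains_xy

    # boundary-inclusive via tiny buffer
    hit = contains_xy(polygon.buffer(1e-9), gx.ravel(), gy.ravel())
    return np.column_stack([gx.ravel()[hit], gy.ravel()[hit]])


def build_domain(config: dict | None = None) -> DomainSpec:
    """Build a DomainSpec from a declarative config dict.

    The config gives grid extent, spacing, origin, geographic anchor, target
    footprint area, an optional explicit footprint mask, and sub-region
    polygons as vertex lists in km.  Release points are the 1 km cell centres
    inside each sub-region polygon; overlapping polygons are rejected so each
    release point belongs to exactly one region.
    """
    cfg = dict(DEMO_CONFIG if config is None else config)
    nx, ny = int(cfg["nx"]), int(cfg["ny"])
    if nx <= 0 or ny <= 0:
        raise ValueError("empty domain: nx and ny must be positive")
    footprint = cfg.get("footprint")
    if footprint is None:
        footprint = np.ones((ny, nx), bool)
    else:
        footprint = np.asarray(footprint, bool)
    release_mask = cfg.get("release_mask")  # optional (ny, nx) bool

    subs = []
    for name, verts in cfg["subregions"].items():
        poly = Polygon(verts)
        pts = _release_points_in(poly, cfg)
        if release_mask is not None:
            i = ((pts[:, 0] - cfg["origin"][0]) / cfg["spacing"]).astype(int)
            j = ((pts[:, 1] - cfg["origin"][1]) / cfg["spacing"]).astype(int)
            pts = pts[np.asarray(release_mask, bool)[j, i]]
        subs.append(SubRegion(name=name, polygon=poly, release_points=pts))
    subs.sort(key=lambda r: REGION_ORDER.index(r.name) if r.name in REGION_ORDER else 99)

    return DomainSpec(
        origin=tuple(cfg["origin"]),
        nx=nx,
        ny=ny,
        spacing=float(cfg["spacing"]),
        footprint=footprint,
        subregions=tuple(subs),
        anchor_lonlat=tuple(cfg["anchor_lonlat"]),
        target_area_km2=float(cfg.get("target_area_km2", 1500.0)),
    )


# -- GeoJSON I/O -----------------------------------------------------------


def subregions_to_geojson(domain: DomainSpec, path: str) -> None:
    """Write sub-region polygons as GeoJSON features (lon/lat coordinates)."""
    feats = []
    for reg in domain.subregions:
        ring = []
        for x, y in reg.polygon.exterior.coords:
            lon, lat = domain.km_to_lonlat(x, y)
            ring.append([float(lon), float(lat)])
        feats.append(
            {
                "type": "Feature",
                "properties": {"name": reg.name},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def subregions_from_geojson(path: str, domain: DomainSpec) -> list[SubRegion]:
    """Read sub-region polygons from GeoJSON, converting lon/lat to km."""
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc["features"]:
        geom = shape(feat["geometry"])
        xs, ys = domain.lonlat_to_km(
            np.array(geom.exterior.coords)[:, 0], np.array(geom.exterior.coords)[:, 1]
        )
        poly = Polygon(np.column_stack([xs, ys]))
        cfg = {
            "nx": domain.nx,
            "ny": domain.ny,
            "spacing": domain.spacing,
            "origin": domain.origin,
        }
        out.append(
            SubRegion(
                name=feat["properties"]["name"],
                polygon=poly,
                release_points=_release_points_in(poly, cfg),
            )
        )
    return out
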