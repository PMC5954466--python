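"""Release-experiment scheduling, e-folding residence time, sub-region
connectivity and the krill grazing-impact arithmetic.

Residence time of a release is the time for the number of particles still
inside the data footprint to fall to 1/e (36.79%) of those released, i.e.
the first hourly log at which cumulative exits reach
``n - round(n / e)`` (round half away from zero; for 84 released particles
that is 53 exits).  Sub-region releases use the sub-region's own release
points but exit is always through the footprint edge.  Connectivity is the
percentage of particles released in one sub-region whose hourly track ever
enters another sub-region (each particle counted once per destination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain_geometry import DomainSpec
from .particle_advection import EXIT_CENSORED, track_batch
from .velocity_field import VelocityFieldSeries

EFOLD_FRACTION = 1.0 / math.e  # 36.79% remaining


@dataclass(frozen=True)
class ReleaseSchedule:
    times: pd.DatetimeIndex

    @property
    def count(self) -> int:
        return len(self.times)


@dataclass
class ResidenceRecord:
    release_time: pd.Timestamp
    region: str
    n_released: int
    residence_days: float | None  # None = censored
    censored: bool
    horizon_days: float


def schedule_releases(start, end, cadence_h: float = 6.0) -> ReleaseSchedule:
    """Release timestamps start, start+cadence, ..., end (both ends included).

    The cadence must divide the interval exactly; otherwise the position of
    the final release would be ambiguous and the call errors out.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end < start:
        raise ValueError("end before start")
    if cadence_h <= 0:
        raise ValueError("cadence must be positive")
    span_h = (end - start) / pd.Timedelta(hours=1)
    k = span_h / cadence_h
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"cadence {cadence_h} h does not divide the {span_h} h interval"
        )
    times = start + pd.to_timedelta(np.arange(round(k) + 1) * cadence_h, unit="h")
    return ReleaseSchedule(times=pd.DatetimeIndex(times))


def efolding_exit_count(n_released: int) -> int:
    """Exits needed to cut the remaining count to the e-folding fraction.

    n - round(n / e), rounding half away from zero, which makes 84 released
    particles need 53 exits (31 = round(30.90) remain).
    """
    if n_released < 1:
        raise ValueError("need at least one released particle")
    remaining = n_released / math.e
    rounded = math.floor(remaining + 0.5)  # half away from zero (n >= 0)
    return n_released - rounded


def exit_count_for_fraction(n_released: int, exited_fraction: float) -> int:
    """Exits needed for an arbitrary exited fraction (e.g. 0.9)."""
    if n_released < 1:
        raise ValueError("need at least one released particle")
    remaining = n_released * (1.0 - exited_fraction)
    return n_released - math.floor(remaining + 0.5)


def residence_time_from_exits(
    exit_times_h: np.ndarray,
    n_released: int,
    horizon_h: float,
    threshold: str | float = "efold",
) -> tuple[float | None, bool]:
    """Residence time (days) from per-particle exit hours (NaN = censored).

    Returns (days, censored): the earliest hourly offset at which cumulative
    exits reach the threshold count, or censored if never reached within the
    record/horizon.
    """
    if threshold == "efold":
        need = efolding_exit_count(n_released)
    else:
        need = exit_count_for_fraction(n_released, float(threshold))
    finite = np.sort(exit_times_h[np.isfinite(exit_times_h)])
    if len(finite) < need:
        return None, True
    return float(finite[need - 1]) / 24.0, False


@dataclass
class ReleaseExperimentResult:
    records: list[ResidenceRecord]
    exit_times: dict  # (release_time, region) -> np.ndarray of exit hours
    batches: list  # per-release track_batch dicts (None if not kept)
    regions: tuple
    schedule: ReleaseSchedule


def run_release_experiments(
    field: VelocityFieldSeries,
    domain: DomainSpec,
    schedule: ReleaseSchedule,
    regions: tuple = ("ALL", "CAN", "JIF", "WIF"),
    dt: float = 0.1,
    horizon_days: float = 10.0,
    threshold: str | float = "efold",
    keep_tracks: bool = True,
    max_gap_hours: int = 3,
    stop_at_threshold: bool = False,
) -> ReleaseExperimentResult:
    """Track the full release grid at every scheduled time and derive
    residence records for the whole domain and each sub-region.

    All release points are advected once per release time; regional records
    are read off the relevant subset of exit times (footprint exit for every
    region).  Set ``keep_tracks=False`` to drop hourly positions (halves
    memory; connectivity then unavailable).  ``stop_at_threshold`` ends each
    release once the whole-grid threshold exit count is reached — only sound
    when the sole region of interest is ALL.
    """
    horizon_h = horizon_days * 24.0
    record_end = field.times[-1]
    bad = [t for t in schedule.times if t > record_end or t < field.times[0]]
    if bad:
        raise ValueError(f"releases outside the field record: {bad}")

    release_xy = np.vstack([r.release_points for r in domain.subregions])
    labels = np.concatenate(
        [np.full(r.n_release, r.name) for r in domain.subregions]
    )
    region_idx = {"ALL": np.arange(len(release_xy))}
    for r in domain.subregions:
        region_idx[r.name] = np.where(labels == r.name)[0]

    records: list[ResidenceRecord] = []
    exit_times: dict = {}
    batches = []
    stop_after = None
    if stop_at_threshold:
        n_all = len(release_xy)
        stop_after = (
            efolding_exit_count(n_all)
            if threshold == "efold"
            else exit_count_for_fraction(n_all, float(threshold))
        )
    for t_rel in schedule.times:
        batch = track_batch(
            field,
            release_xy,
            t_rel,
            dt=dt,
            horizon_h=horizon_h,
            max_gap_hours=max_gap_hours,
            log_positions=keep_tracks,
            stop_after_exits=stop_after,
        )
        eff_horizon_h = batch["n_hours"]
        for reg in regions:
            idx = region_idx[reg]
            et = batch["exit_time_h"][idx]
            exit_times[(t_rel, reg)] = et
            days, cens = residence_time_from_exits(
                et, len(idx), eff_horizon_h, threshold=threshold
            )
            records.append(
                ResidenceRecord(
                    release_time=t_rel,
                    region=reg,
                    n_released=len(idx),
                    residence_days=days,
                    censored=cens,
                    horizon_days=eff_horizon_h / 24.0,
                )
            )
        batches.append(batch if keep_tracks else None)
    return ReleaseExperimentResult(
        records=records,
        exit_times=exit_times,
        batches=batches,
        regions=tuple(regions),
        schedule=schedule,
    )


def residence_table(result: ReleaseExperimentResult, velocity_kind: str = "raw") -> pd.DataFrame:
    """Per-region summary (mean ± sd, max, min over releases); censored
    releases are excluded from the statistics and counted separately."""
    rows = []
    for reg in result.regions:
        recs = [r for r in result.records if r.region == reg]
        vals = np.array([r.residence_days for r in recs if not r.censored], float)
        n_particles = sum(r.n_released for r in recs)
        rows.append(
            {
                "region": reg,
                "n_particles": n_particles,
                "velocity_kind": velocity_kind,
                "n_releases": len(recs),
                "n_censored": sum(r.censored for r in recs),
                "mean_days": vals.mean() if len(vals) else np.nan,
                "sd_days": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "max_days": vals.max() if len(vals) else np.nan,
                "min_days": vals.min() if len(vals) else np.nan,
                "censor_horizon_days": max(r.horizon_days for r in recs),
            }
        )
    return pd.DataFrame(rows)


def residence_series(result: ReleaseExperimentResult, region: str = "ALL") -> pd.DataFrame:
    rows = [
        {
            "release_time": r.release_time,
            "residence_days": r.residence_days,
            "censored": r.censored,
        }
        for r in result.records
        if r.region == region
    ]
    return pd.DataFrame(rows)


# -- connectivity ----------------------------------------------------------


def connectivity(
    result: ReleaseExperimentResult, domain: DomainSpec
) -> pd.DataFrame:
    """Per-release source->destination connectivity percentages.

    A source particle "enters" a destination sub-region if any of its hourly
    logged positions (release included) lies inside the destination polygon;
    re-entries count once.  Source->source pairs are excluded by
    construction.
    """
    if any(b is None for b in result.batches):
        raise ValueError("connectivity needs keep_tracks=True track storage")
    labels = np.concatenate(
        [np.full(r.n_release, r.name) for r in domain.subregions]
    )
    names = [r.name for r in domain.subregions]
    rows = []
    for t_rel, batch in zip(result.schedule.times, result.batches):
        logged = batch["positions"]  # (nh+1, n, 2)
        nh1, n, _ = logged.shape
        entered = {dest: np.zeros(n, bool) for dest in names}
        flat = logged.reshape(-1, 2)
        ok = np.isfinite(flat[:, 0])
        for dest in names:
            hit = np.zeros(len(flat), bool)
            hit[ok] = domain.locate_many(flat[ok], dest)
            entered[dest] = hit.reshape(nh1, n).any(axis=0)
        for src in names:
            src_idx = labels == src
            n_src = src_idx.sum()
            for dest in names:
                if dest == src:
                    continue
                pct = 100.0 * entered[dest][src_idx].sum() / n_src
                rows.append(
                    {
                        "release_time": t_rel,
                        "source": src,
                        "destination": dest,
                        "percent": pct,
                    }
                )
    return pd.DataFrame(rows)


def connectivity_summary(conn: pd.DataFrame) -> pd.DataFrame:
    g = conn.groupby(["source", "destination"])["percent"]
    out = g.agg(mean="mean", sd="std", max="max", min="min").reset_index()
    return out


# -- grazing impact --------------------------------------------------------


def grazing_impact(ingestion_rate_ug: float, abundance_per_m3: float) -> float:
    """Krill grazing impact in mg Chl a m^-3 day^-1, reported to one decimal.

    ingestion_rate_ug is per-individual daily chlorophyll ingestion
    (ug Chl a ind^-1 day^-1); abundance is individuals per m^3.
    """
    if ingestion_rate_ug < 0 or abundance_per_m3 < 0:
        raise ValueError("inputs must be non-negative")
    return round(ingestion_rate_ug * abundance_per_m3 / 1000.0, 1)
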