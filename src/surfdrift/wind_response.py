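"""Wind merging, residence-window averaging, model-II major-axis regression,
binned distributions and Tukey-Kramer pairwise comparisons.

Two-station winds are merged by vector averaging per timestamp (merged speed
is the magnitude of the mean vector, so opposing winds cancel; a scalar-speed
average is available for sensitivity checks).  Each release's wind statistic
averages the merged series over exactly that release's residence window.
The wind-speed/residence-time relationship uses major-axis (model II)
regression, appropriate because both variables carry error; its slope equals
the direction of the first principal axis of the sample covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import WindSeries


def _to_vectors(speed, direction_from_deg):
    """Wind vector components (toward-direction) from speed and FROM-bearing."""
    th = np.deg2rad(np.mod(np.asarray(direction_from_deg) + 180.0, 360.0))
    return speed * np.sin(th), speed * np.cos(th)


def _from_vectors(u, v):
    speed = np.hypot(u, v)
    # bearing the wind comes FROM
    direction = np.mod(np.rad2deg(np.arctan2(-u, -v)), 360.0)
    return speed, direction


def merge_winds(a: WindSeries, b: WindSeries, how: str = "vector") -> WindSeries:
    """Average two station series on their common 15-min timestamps.

    ``how='vector'`` (default): components averaged per timestamp; merged
    speed is the magnitude of the mean vector and the direction follows the
    mean vector (NaN where the vectors cancel exactly).  ``how='scalar'``
    averages speeds arithmetically while still taking direction from the
    mean vector.
    """
    common = a.times.intersection(b.times)
    if len(common) == 0:
        raise ValueError("wind series do not overlap in time")
    ia = a.times.get_indexer(common)
    ib = b.times.get_indexer(common)
    ua, va = _to_vectors(a.speed_ms[ia], a.direction_deg[ia])
    ub, vb = _to_vectors(b.speed_ms[ib], b.direction_deg[ib])
    u, v = 0.5 * (ua + ub), 0.5 * (va + vb)
    speed, direction = _from_vectors(u, v)
    direction = np.where(speed > 1e-12, direction, np.nan)
    if how == "scalar":
        speed = 0.5 * (a.speed_ms[ia] + b.speed_ms[ib])
    elif how != "vector":
        raise ValueError("how must be 'vector' or 'scalar'")
    return WindSeries(
        station="merged", times=common, speed_ms=speed, direction_deg=direction
    )


def window_mean(wind: WindSeries, t0, duration_days: float):
    """Mean speed, circular-mean direction and speed sd over a residence
    window [t0, t0 + duration], inclusive of both ends at the 15-min cadence.
    """
    t0 = pd.Timestamp(t0)
    t1 = t0 + pd.Timedelta(days=float(duration_days))
    if t0 < wind.times[0] or t1 > wind.times[-1]:
        raise ValueError("averaging window extends beyond the wind record")
    sel = (wind.times >= t0) & (wind.times <= t1)
    sp = wind.speed_ms[sel]
    dr = wind.direction_deg[sel]
    ok = np.isfinite(dr)
    u, v = _to_vectors(np.ones(ok.sum()), dr[ok])
    mean_dir = _from_vectors(u.mean(), v.mean())[1] if ok.any() else np.nan
    return float(sp.mean()), float(mean_dir), float(sp.std(ddof=1)) if len(sp) > 1 else 0.0


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    ci_lo: float
    ci_hi: float
    r2: float
    p_value: float
    n: int


def major_axis_fit(x, y, confidence: float = 0.95) -> RegressionResult:
    """Model-II major-axis regression of y on x.

    The slope is the direction of the first principal axis of the sample
    covariance matrix,
    b = (s_yy - s_xx + sqrt((s_yy - s_xx)^2 + 4 s_xy^2)) / (2 s_xy),
    with the Jolicoeur confidence interval obtained by rotating the axis by
    atan(A), A = sqrt(H / (1 - H)),
    H = t^2 / ((l1/l2 + l2/l1 - 2) (n - 2)) with l1 >= l2 the covariance
    eigenvalues.  r^2 is the squared Pearson correlation and the p-value
    comes from the correlation t-test.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = x.var(ddof=1)
    syy = y.var(ddof=1)
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx == 0 or syy == 0:
        raise ValueError("degenerate sample: a variable has zero variance")
    if sxy == 0:
        if np.isclose(sxx, syy):
            raise ValueError("major-axis slope undefined: circular scatter")
        slope = 0.0 if sxx > syy else np.inf
    else:
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    intercept = y.mean() - slope * x.mean()

    r, p = stats.pearsonr(x, y)
    r2 = float(r**2)

    cov = np.array([[sxx, sxy], [sxy, syy]])
    l1, l2 = np.sort(np.linalg.eigvalsh(cov))[::-1]
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 2)
    if l2 <= 0:
        ci_lo = ci_hi = slope  # perfectly collinear sample
    else:
        H = tcrit**2 / ((l1 / l2 + l2 / l1 - 2.0) * (n - 2))
        if H >= 1:
            ci_lo, ci_hi = -np.inf, np.inf
        else:
            A = np.sqrt(H / (1.0 - H))
            lo = (slope - A) / (1.0 + slope * A)
            hi = (slope + A) / (1.0 - slope * A)
            if slope * A >= 1.0:  # CI wraps through the vertical
                hi = np.inf
            ci_lo, ci_hi = min(lo, hi), max(lo, hi)
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        ci_lo=float(ci_lo),
        ci_hi=float(ci_hi),
        r2=r2,
        p_value=float(p),
        n=n,
    )


@dataclass
class BinnedSummary:
    bin_center: float
    members: np.ndarray
    median: float
    sd: float
    range: tuple[float, float]
    n: int


def speed_bin(speed) -> np.ndarray:
    """1 m/s centred bins: bin k covers [k - 0.5, k + 0.5)."""
    return np.floor(np.asarray(speed, float) + 0.5).astype(int)


def direction_bin(direction_deg, width: float = 30.0) -> np.ndarray:
    """Centred direction bins {0, 30, ..., 330} with wraparound at 360."""
    d = np.asarray(direction_deg, float)
    return (np.floor(d / width + 0.5).astype(int) * int(width)) % 360


def binned_distributions(
    wind_stat, residence_days, mode: str = "speed"
) -> list[BinnedSummary]:
    """Group residence times by wind-speed or wind-direction bin."""
    wind_stat = np.asarray(wind_stat, float)
    residence_days = np.asarray(residence_days, float)
    ok = np.isfinite(wind_stat) & np.isfinite(residence_days)
    if not ok.any():
        raise ValueError("no valid pairs to bin")
    wind_stat, residence_days = wind_stat[ok], residence_days[ok]
    if mode == "speed":
        keys = speed_bin(wind_stat)
    elif mode == "direction":
        keys = direction_bin(wind_stat)
    else:
        raise ValueError("mode must be 'speed' or 'direction'")
    out = []
    for k in np.unique(keys):
        m = residence_days[keys == k]
        out.append(
            BinnedSummary(
                bin_center=float(k),
                members=m,
                median=float(np.median(m)),
                sd=float(m.std(ddof=1)) if len(m) > 1 else 0.0,
                range=(float(m.min()), float(m.max())),
                n=len(m),
            )
        )
    return out


def tukey_pairwise(
    groups: dict, min_group_size: int = 2, alpha: float = 0.05
) -> tuple[pd.DataFrame, list]:
    """Tukey-Kramer HSD comparisons across bins.

    ``groups`` maps bin label -> residence-time samples.  Groups below
    ``min_group_size`` are excluded and returned in the second element
    (bins with too few samples to be meaningfully tested).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    kept = {k: np.asarray(v, float) for k, v in groups.items() if len(v) >= min_group_size}
    excluded = [k for k in groups if k not in kept]
    if len(kept) < 2:
        raise ValueError("fewer than two groups large enough to compare")
    data = np.concatenate(list(kept.values()))
    labels = np.concatenate([np.full(len(v), str(k)) for k, v in kept.items()])
    res = pairwise_tukeyhsd(data, labels, alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    return table, excluded


def wind_residence_table(
    merged: WindSeries,
    residence: pd.DataFrame,
    region: str = "ALL",
) -> pd.DataFrame:
    """Per-release (wind, residence) pairs: each release's merged wind
    averaged over exactly its residence window.  Censored releases are
    dropped (and counted in the ``n_censored`` attribute)."""
    rows = []
    n_cens = 0
    for _, rec in residence.iterrows():
        if rec.get("censored", False) or not np.isfinite(rec["residence_days"] or np.nan):
            n_cens += 1
            continue
        sp, dr, sd = window_mean(merged, rec["release_time"], rec["residence_days"])
        rows.append(
            {
                "release_time": rec["release_time"],
                "residence_days": rec["residence_days"],
                "wind_speed_ms": sp,
                "wind_dir_deg": dr,
                "wind_speed_sd": sd,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_censored"] = n_cens
    out.attrs["region"] = region
    return out


def regression_table(pairs_by_region: dict) -> pd.DataFrame:
    """Slope/CI/p/r2 table across regions from per-region pair frames."""
    rows = []
    for region, pairs in pairs_by_region.items():
        fit = major_axis_fit(pairs["wind_speed_ms"], pairs["residence_days"])
        rows.append(
            {
                "region": region,
                "slope": fit.slope,
                "ci_lo": fit.ci_lo,
                "ci_hi": fit.ci_hi,
                "p_value": fit.p_value,
                "r2": fit.r2,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)
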