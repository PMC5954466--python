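"""Least-squares tidal harmonic analysis and de-tiding.

Per grid point and velocity component, the raw series is regressed on a
constant plus cosine/sine pairs at fixed astronomical constituent
frequencies; gap samples are simply dropped from the normal equations.  The
de-tided series is raw minus the fitted tidal part (the constant mean is NOT
counted as tide), so raw = mean-plus-tide + residual holds exactly at every
fitted sample and all non-tidal high-frequency variability is retained.

Constituent significance: the (cos, sin) coefficient pair is tested jointly
with an exact F-test at the requested confidence.  Amplitude confidence
intervals are also reported via linearised propagation of the coefficient
covariance; at low signal-to-noise the linearised CI is approximate, which
is why the significance flag comes from the F-test rather than the CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_data import constituent_frequencies
from .velocity_field import VelocityFieldSeries

DEFAULT_CONSTITUENTS = ("O1", "K1", "M2", "S2")


@dataclass
class ConstituentFit:
    name: str
    omega_rad_h: float
    cos_coef: float
    sin_coef: float
    amplitude: float
    phase_deg: float
    ci_lo: float
    ci_hi: float
    p_value: float
    significant: bool


@dataclass
class TidalFitResult:
    """Harmonic fit of one scalar series.

    ``fitted`` is the tidal part only (significant constituents, mean
    excluded); ``residual`` = series - mean - fitted, so
    series = mean + fitted + residual exactly wherever the sample was valid.
    """

    constituents: list[ConstituentFit]
    mean: float
    fitted: np.ndarray
    residual: np.ndarray
    variance_explained: float

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "constituent": c.name,
                    "amplitude": c.amplitude,
                    "phase_deg": c.phase_deg,
                    "ci_lo": c.ci_lo,
                    "ci_hi": c.ci_hi,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in self.constituents
            ]
        )


def _check_resolvable(freqs: dict[str, float], t_hours: np.ndarray):
    span = t_hours.max() - t_hours.min()
    names = list(freqs)
    fastest = max(freqs.values())
    if len(t_hours) > 1:
        cadence = np.median(np.diff(np.sort(t_hours)))
        if cadence > np.pi / fastest:  # < 2 samples per cycle
            raise ValueError("sampling slower than the Nyquist rate of the fastest constituent")
    slowest = min(freqs.values())
    if span < 2 * np.pi / slowest:
        warnings.warn("record shorter than one cycle of the slowest constituent", stacklevel=3)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            dw = abs(freqs[names[a]] - freqs[names[b]])
            if dw == 0.0:
                raise ValueError(f"duplicate constituent frequency: {names[a]}/{names[b]}")
            if dw * span < 2 * np.pi:
                warnings.warn(
                    f"Rayleigh criterion violated for pair {names[a]}/{names[b]}: "
                    f"record too short to separate them",
                    stacklevel=3,
                )


def harmonic_fit(
    series: np.ndarray,
    t_hours: np.ndarray,
    constituents=DEFAULT_CONSTITUENTS,
    confidence: float = 0.95,
) -> TidalFitResult:
    """Fit mean + sum of harmonics to an evenly sampled series with gaps.

    Parameters
    ----------
    series : 1-D array; NaN marks gap samples, which are dropped.
    t_hours : sample times in hours (same length).
    constituents : names from the built-in Darwin table, or a mapping
        name -> angular frequency (rad/h).
    confidence : level for the amplitude CIs and the significance F-test.
    """
    series = np.asarray(series, float)
    t_hours = np.asarray(t_hours, float)
    if isinstance(constituents, dict):
        freqs = dict(constituents)
    else:
        freqs = constituent_frequencies(constituents)
    valid = np.isfinite(series)
    y = series[valid]
    t = t_hours[valid]
    n = len(y)
    p = 1 + 2 * len(freqs)
    if n < p:
        raise ValueError(f"only {n} valid samples for {p} coefficients")
    _check_resolvable(freqs, t)

    cols = [np.ones(n)]
    for w in freqs.values():
        cols += [np.cos(w * t), np.sin(w * t)]
    X = np.column_stack(cols)

    # guard against numerically unresolvable pairs (near-collinear columns)
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise ValueError(
            "rank-deficient harmonic basis (unresolvable frequency pair for "
            f"this record length); condition number {cond:.2e}"
        )

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    resid = y - yhat
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * XtX_inv
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof) if dof > 0 else np.inf
    fcrit_level = 1.0 - confidence

    fits = []
    tidal_signif = np.zeros(n)
    for k, (name, w) in enumerate(freqs.items()):
        ia, ib = 1 + 2 * k, 2 + 2 * k
        a, b = beta[ia], beta[ib]
        amp = float(np.hypot(a, b))
        phase = float(np.rad2deg(np.arctan2(b, a)) % 360.0)
        va, vb, cab = cov[ia, ia], cov[ib, ib], cov[ia, ib]
        if amp > 0 and sigma2 > 0:
            se_amp = np.sqrt(max((a * a * va + b * b * vb + 2 * a * b * cab), 0.0)) / amp
        else:
            se_amp = np.sqrt(max(0.5 * (va + vb), 0.0))
        ci_lo = max(amp - tcrit * se_amp, 0.0)
        ci_hi = amp + tcrit * se_amp
        # joint F-test on the (cos, sin) pair
        sub = cov[np.ix_([ia, ib], [ia, ib])]
        if sigma2 > 0 and dof > 0:
            F = float(np.array([a, b]) @ np.linalg.solve(sub, np.array([a, b]))) / 2.0
            pval = float(stats.f.sf(F, 2, dof))
        else:
            pval = 0.0 if amp > 0 else 1.0
        signif = pval < fcrit_level
        if signif:
            tidal_signif += a * np.cos(w * t) + b * np.sin(w * t)
        fits.append(
            ConstituentFit(
                name=name,
                omega_rad_h=w,
                cos_coef=float(a),
                sin_coef=float(b),
                amplitude=amp,
                phase_deg=phase,
                ci_lo=float(ci_lo),
                ci_hi=float(ci_hi),
                p_value=pval,
                significant=bool(signif),
            )
        )

    fitted_full = np.full_like(series, np.nan)
    residual_full = np.full_like(series, np.nan)
    fitted_full[valid] = tidal_signif
    residual_full[valid] = y - beta[0] - tidal_signif

    ss_raw = float(np.sum((y - y.mean()) ** 2))
    ss_tide = float(np.sum((tidal_signif - tidal_signif.mean()) ** 2))
    var_expl = 0.0 if ss_raw <= 0 else min(ss_tide / ss_raw, 1.0)

    return TidalFitResult(
        constituents=fits,
        mean=float(beta[0]),
        fitted=fitted_full,
        residual=residual_full,
        variance_explained=var_expl,
    )


def detide_field(
    field: VelocityFieldSeries,
    constituents=DEFAULT_CONSTITUENTS,
    confidence: float = 0.95,
    min_valid_samples: int | None = None,
    analysis_window: tuple | None = None,
):
    """De-tide every grid cell of a velocity-field series.

    Returns ``(detided_field, variance_explained)`` where the de-tided series
    keeps each cell's mean and non-tidal variability (raw minus tidal fit)
    and the pooled variance_explained is total tidal-fit variance over total
    raw variance across all fitted cell-hours and both components.  Cells
    with fewer than ``min_valid_samples`` valid hours (default: 4x the
    coefficient count) are passed through unfitted and reported in
    ``detided.attrs``-style bookkeeping on the returned field (``unfitted``
    attribute).

    ``analysis_window=(start, end)`` optionally trims the *returned* series
    to a subwindow after fitting on the full record, mirroring a fit window
    longer than the analysis window.
    """
    if isinstance(constituents, dict):
        freqs = dict(constituents)
    else:
        freqs = constituent_frequencies(constituents)
    nt, ny, nx = field.u.shape
    t_hours = (
        (field.times - field.times[0]) / np.timedelta64(1, "h")
    ).to_numpy(float)
    p = 1 + 2 * len(freqs)
    if min_valid_samples is None:
        min_valid_samples = 4 * p

    u_out = field.u.copy()
    v_out = field.v.copy()
    ss_tide = 0.0
    ss_raw = 0.0
    unfitted = []

    for j in range(ny):
        for i in range(nx):
            m = field.mask[:, j, i]
            if m.sum() < min_valid_samples:
                if field.domain.footprint[j, i]:
                    unfitted.append((i, j))
                continue
            for comp, arr, out in (("u", field.u, u_out), ("v", field.v, v_out)):
                y = np.where(m, arr[:, j, i], np.nan)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = harmonic_fit(y, t_hours, freqs, confidence)
                out[m, j, i] = arr[m, j, i] - res.fitted[m]
                yv = y[m]
                ss_raw += float(np.sum((yv - yv.mean()) ** 2))
                ss_tide += float(np.sum((res.fitted[m] - res.fitted[m].mean()) ** 2))

    variance_explained = 0.0 if ss_raw <= 0 else ss_tide / ss_raw

    out_field = VelocityFieldSeries(
        times=field.times, u=u_out, v=v_out, mask=field.mask.copy(), domain=field.domain
    )
    out_field.unfitted_cells = unfitted
    if analysis_window is not None:
        out_field = out_field.subwindow(*analysis_window)
        out_field.unfitted_cells = unfitted
    return out_field, variance_explained


def constituent_table_csv(results: dict[str, TidalFitResult], path: str) -> None:
    """Write per-component constituent tables as one CSV."""
    import pandas as pd

    rows = []
    for comp, res in results.items():
        t = res.table()
        t.insert(0, "component", comp)
        rows.append(t)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
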