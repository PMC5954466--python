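# surfdrift

Surface residence time, sub-region connectivity and wind response of a
coastal biological hotspot, computed from hourly gridded surface-current
maps by Lagrangian particle tracking.

## The problem

Submarine canyons along the West Antarctic Peninsula — Palmer Deep is the
type case — hold persistently elevated phytoplankton and krill biomass that
feeds penguin colonies. Whether such a canyon acts as an *incubator*
(retaining and locally growing biomass) or a *conveyor belt* (continually
importing and flushing biomass) hinges on how long a parcel of surface water
stays over the canyon. Shore-based high-frequency radar (HFR) networks map
surface currents hourly on a ~1 km grid over ~1500 km² of ocean, which is
exactly the substrate needed to answer that question with passive-particle
experiments.

`surfdrift` implements that analysis chain as a tested, reusable library:

- **Domain geometry** — a 1 km release grid over the radar footprint with
  canyon (CAN) and island-flank (JIF, WIF) sub-region polygons; the bundled
  demo geometry carries 187/84/61 release points (332 total).
- **Synthetic data** — a seeded generator for HFR-like current maps (mean
  coastal current + O1/K1/M2/S2 tidal harmonics + wind-coupled component +
  a divergence-free random-streamfunction eddy field + ~3% coverage gaps)
  and correlated two-station 15-minute winds, so the entire pipeline is
  exercisable without any proprietary data.
- **Tidal analysis** — per-cell least-squares harmonic fits, constituent
  significance screening, pooled variance explained, and de-tided series
  with the exact decomposition `raw = mean + tide + residual`.
- **Particle advection** — classical 4th-order Runge–Kutta through a field
  interpolated bilinearly in space (weights renormalised over valid cells)
  and linearly in time; hourly position logs; exit at the first hourly log
  outside the footprint.
- **Hotspot metrics** — 6-hourly release scheduling, e-folding residence
  time, sub-region connectivity percentages, and the krill grazing-impact
  arithmetic.
- **Wind response** — vector-merged station winds, per-release residence-
  window averaging, model-II major-axis regression with Jolicoeur CIs,
  1 m s⁻¹ / 30° binned distributions, and Tukey–Kramer comparisons.

## The statistic

For one release of `n` particles, the residence time is the first hourly
log at which the number of particles remaining in the footprint has dropped
to the e-folding fraction `1/e ≈ 36.79%` of `n`, i.e. after
`n − round(n/e)` exits (53 exits of 84 released). The wind relationship is
quantified with major-axis (model II) regression,

```
b = (s_yy − s_xx + sqrt((s_yy − s_xx)² + 4 s_xy²)) / (2 s_xy)
```

appropriate because wind speed and residence time both carry error.

## Worked example

```python
import surfdrift as sd
from surfdrift.synthetic_data import SynthConfig
from surfdrift.tidal_analysis import detide_field
from surfdrift.hotspot_metrics import (
    schedule_releases, run_release_experiments, residence_table,
    connectivity, connectivity_summary,
)

domain = sd.build_domain()                      # 50 x 30 km demo footprint, 332 release points
cfg = SynthConfig(duration_days=12.0, seed=3, tidal_variance_fraction=0.123)
field = sd.synth_currents(cfg, domain)          # hourly u, v maps, 3% gaps

detided, var_expl = detide_field(field)
print(f"tidal variance explained: {100 * var_expl:.1f}%")

sched = schedule_releases("2015-01-01", "2015-01-03", cadence_h=6.0)
res = run_release_experiments(field, domain, sched, horizon_days=10.0)
print(residence_table(res)[["region", "mean_days", "sd_days", "max_days", "min_days"]].round(2))
print(connectivity_summary(connectivity(res, domain)).round(1))
```

prints

```
tidal variance explained: 9.7%
region  mean_days  sd_days  max_days  min_days
   ALL       1.62     0.13      1.88      1.42
   CAN       1.71     0.13      1.92      1.50
   JIF       1.71     0.13      2.00      1.54
   WIF       1.25     0.12      1.50      1.12
source destination  mean   sd  max  min
   CAN         JIF   0.0  0.0  0.0  0.0
   CAN         WIF  34.2 11.9 47.1 16.6
   JIF         CAN  71.4 16.8 94.0 47.6
   JIF         WIF   0.7  1.3  3.6  0.0
   WIF         CAN   0.0  0.0  0.0  0.0
   WIF         JIF   0.0  0.0  0.0  0.0
```

Mean surface residence here is about 1.6 days with the western flank
flushing fastest, and the eastward mean current carries JIF water across
the canyon (JIF→CAN 71%) while almost nothing moves upstream — the
directional asymmetry the connectivity table is designed to expose. The
9.7% tidal share on this short 12-day demo record sits below the
configured 12.3% because a 12-day fit resolves the constituent pairs less
cleanly than the month-plus records the full runs use.

There is also a CLI for shell use:

```bash
surfdrift simulate --out field.nc --winds-out winds
surfdrift detide --in field.nc --out detided.nc --constituents O1,K1,M2,S2
surfdrift run-all --config run.yaml --out run_out/
```

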