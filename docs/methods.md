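# Methods

This note documents the models, conventions and numerical choices behind
`surfdrift`, in the spirit of a model-description appendix: what is
computed, under which assumptions, and what the synthetic experiments do
and do not demonstrate.

## Coordinates and domain

All computation happens in a local tangent-plane Cartesian frame in km,
obtained by an equirectangular projection about a geographic anchor;
longitude/latitude appear only in GeoJSON and track exports. This keeps
advection, point-in-polygon tests and areas in metric space; over a
~50 km domain at 65°S the projection distortion is negligible relative to
the 1 km grid.

The demo geometry is schematic: a 50 × 30 km rectangular footprint
(1500 cells of 1 km², matching the ~1500 km² coverage of a three-site HFR
network) with a central-canyon rectangle flanked by two island-flank
polygons whose 1 km release grids carry 187 (CAN), 84 (JIF) and 61 (WIF)
points — the published split of the 332-point release grid, which is the
only geometric constraint available; the true polygons are not published as
coordinates. Polygon membership is boundary-inclusive and ties on shared
edges are broken by the fixed ordering CAN→JIF→WIF, making `locate`
deterministic. An optional release mask can thin the release grid (e.g. to
mimic excluded near-shore cells) without touching the polygons.

## Synthetic current and wind generator

The generator emulates the statistical structure the analysis assumes, not
any particular ocean state. Hourly velocity maps are the sum of

- a constant mean current (default 12 cm s⁻¹ eastward — a persistent
  coastal current);
- tidal harmonics at the four most energetic diurnal/semi-diurnal
  constituents, with Darwin periods hard-coded (M2 12.4206 h, S2 12 h,
  K1 23.9345 h, O1 25.8193 h) and no nodal corrections — sufficient for
  validating de-tiding, which is the purpose;
- a wind-coupled component: a fraction (default 3%) of the latent wind
  speed, directed downwind with a configurable deflection; with constant
  wind `W` and coupling `c` this component is exactly `c·W` by
  construction;
- a mesoscale eddy field: the analytic curl of a random-Fourier-mode
  streamfunction (default 8 modes around a 12 km length scale) whose mode
  amplitudes evolve as an AR(1) process (36 h time scale), normalised to a
  target rms speed (default 6 cm s⁻¹). Because u, v derive analytically
  from a streamfunction, the continuum field is exactly divergence-free;

plus an i.i.d. Bernoulli coverage mask (default 3% gaps, i.e. 97% mean
coverage). When `tidal_variance_fraction` is set, the tidal amplitudes are
rescaled once so the tidal share of total variance over the record equals
the target (the observational value is 12.3%).

Winds: a latent 15-minute wind (AR(1) red-noise speed about a 6 m s⁻¹ mean
with 2.5 m s⁻¹ sd and 36 h decorrelation — spanning the observed 2–12
m s⁻¹ range — and a random-walk FROM-direction, clockwise from true north)
is observed by two stations with small AR(1) speed noise and direction
jitter. The same latent wind drives the wind-coupled current, so the
wind→residence coupling survives the two-station merge. All randomness
derives from a single seed split per component; identical configs are
bitwise-reproducible.

Known departures from real HFR data, hence limits on what passing tests
show: gaps are spatially i.i.d. where real gaps are coherent (antenna
outages, range cutoffs); the eddy spectrum is a few Fourier modes, not a
turbulent cascade; there is no horizontal shear in the mean current; wind
coupling is instantaneous and spatially uniform. The pipeline's
statistical behaviour under these idealisations says nothing about, e.g.,
gap-pattern biases in real radar data.

## Tidal harmonic analysis

Per grid cell and velocity component, the series is regressed by ordinary
least squares on `[1, cos ωᵢt, sin ωᵢt]`; gap samples are dropped from the
normal equations, never interpolated. The constant term is always included
and never counted as tidal variance. Sampling slower than the fastest
constituent's Nyquist rate is an error; a record shorter than a cycle of
the slowest constituent, or than the Rayleigh separation of a constituent
pair, warns; a numerically rank-deficient basis (condition number > 1e8)
is an error naming the cause.

Significance of a constituent is the exact joint F-test on its (cos, sin)
coefficient pair at the requested confidence; amplitude confidence
intervals are additionally reported by linearised propagation of the
coefficient covariance (`se(A)² = (a²σ_a² + b²σ_b² + 2ab σ_ab)/A²`). At
low signal-to-noise the linearised CI is conservative-to-wrong (the
amplitude estimator is Rayleigh-distributed under the null), which is why
the significance flag uses the F-test: Monte Carlo on pure noise confirms
its false-positive rate sits at the nominal level per constituent.
Insignificant constituents are zeroed out of the fitted tidal series.

De-tiding subtracts the fitted tidal part, so `raw = mean + tide +
residual` holds exactly at every fitted sample and all non-tidal
variability is retained. The pooled variance explained is the ratio of
summed tidal-fit variance to summed raw variance over all fitted
cell-hours and both components. Cells with fewer valid samples than four
times the coefficient count are passed through unfitted and reported.
Fitting may use a longer window than the analysis (fit December–May,
analyse January–February); requesting an analysis window is exactly
equivalent to post-hoc extraction from the full de-tided series.

## Particle advection

Velocities are cm s⁻¹ at I/O and converted once to km h⁻¹ (1 cm s⁻¹ =
0.036 km h⁻¹). Sampling is bilinear among the four surrounding cell
centres with weights renormalised over valid cells (so a single missing
neighbour biases nothing in a locally uniform flow), and linear in time
between bracketing hourly maps; if only one bracketing map has valid data
it is used alone, and with none the particle receives a no-data signal.
Integration is classical RK4 with an internal step of 0.1 h by default;
a convergence test verifies 4th-order error scaling on a solid-body
rotation orbit (error ratio ≈ 16 per step halving; radius drift < 1 m over
a 12 h period).

Exit is evaluated at hourly log points only, matching the hourly
observation cadence: sub-hour excursions beyond the footprint that return
before the next log are not exits. A particle whose velocity is
unsampleable at any RK4 stage freezes for the remainder of that hour; more
than 3 consecutive such hours terminates it with reason
`entered_persistent_gap`, counted as having left the footprint (a
judgement call — the alternative, holding particles indefinitely in dead
zones, inflates residence with unobserved water). Releases outside the
footprint are rejected.

Two code paths produce trajectories: a reference pure-numpy path
(`sample_velocity`/`rk4_step`) and a compiled per-hour kernel used by
`track_batch` for hourly-aligned fields; a test asserts they agree to
~1e-14 km.

## Residence time, connectivity, grazing

Releases run on a 6 h cadence, both endpoints included (1 Jan–1 Mar gives
237 releases; 237 × 332 = 78 684 tracked particles for the whole domain).
The e-folding exit count is `n − round(n/e)` with round-half-away-from-zero
— the integerisation that makes 84 released particles need 53 exits, as the
published worked example requires; strictly-below-remaining semantics would
give 54 and is rejected for that reason. Sub-region releases use that
region's own release points but always footprint exit. Releases whose
threshold is never reached within the horizon (default 10 days) or record
are censored: excluded from means and SDs, counted, and reported with
their horizon. Raising the threshold to 90% exited can only lengthen
residence; this monotonicity is asserted per release.

Connectivity counts a source particle at most once per destination no
matter how often it re-enters, using every hourly logged position
including the release point; source→source pairs are excluded by
construction.

Grazing impact is the product of a per-individual daily chlorophyll
ingestion rate (µg Chl a ind⁻¹ day⁻¹) and a krill abundance (ind m⁻³),
reported in mg Chl a m⁻³ day⁻¹ to one decimal (6.37 × 87 → 0.6;
6.37 × 2168 → 13.8).

## Wind response

Station winds are merged by vector averaging on common timestamps; merged
speed is the magnitude of the mean vector (opposing winds cancel to zero
speed with undefined direction), with scalar-speed averaging available as
a sensitivity option. Each release's wind statistic averages the merged
series over exactly `[t_release, t_release + residence]`, inclusive of
both ends at the 15-minute cadence; direction uses the circular mean. A
published worked example implies a window end 9 minutes past `t0 + 1.9 d`;
the inclusive-ends rule here is documented rather than reverse-engineered
(a 1.9-day window's last sample falls at 45.5 h).

Major-axis regression takes the slope from the first principal axis of
the sample covariance, with the Jolicoeur confidence interval (rotate the
axis by `atan(A)`, `A = sqrt(H/(1−H))`,
`H = t²/((λ₁/λ₂ + λ₂/λ₁ − 2)(n−2))`); r² is the squared Pearson
correlation and the p-value its t-test. Degenerate inputs (zero variance,
circular scatter) are errors. Speed bins are 1 m s⁻¹ centred half-open
intervals; direction bins are 30° centred with wraparound (359° → bin 0,
15° → bin 30). Tukey–Kramer comparisons run across bins with at least two
members; smaller bins are excluded and reported.

## Recovery experiments and problem sizes

The statistical acceptance experiments run at a reduced scale chosen to
exercise every stage with comfortable margins: a 20 × 20 km domain with 68
release points (32/18/18 per region), 30-day records, 101 6-hourly
releases, 5-day horizons. Tidal-share recovery checks the pooled variance
explained against the configured 12.3% within 2 percentage points.

Slope recovery runs the complete pipeline (currents + winds → tracking →
residence → window-averaged winds → major-axis fit) over 20 seeded
replicates. Because the residence–wind-speed relation induced by a finite
domain is mildly convex and each wind realisation samples the speed range
differently, there is no closed-form "true" slope; the reference for each
replicate is instead the same pipeline with the same latent wind but the
stochastic elements (eddies, coverage gaps, station noise) switched off.
The replicate's 95% CI must cover its noise-free reference in at least 90%
of replicates. This isolates exactly the question the regression answers —
does noisy data recover the wind-driven signal — without conflating it
with the curvature of the underlying response.

## Known limitations

- The amplitude CI and the F-test significance flag can disagree near the
  detection threshold; the flag is authoritative.
- Exit detection at hourly logs quantises residence to 1/24 day.
- The gap-termination rule (> 3 h without data → counted as exited) is a
  convention; with 3% i.i.d. gaps it affects well under 1% of particles,
  but spatially coherent real-world gaps could make it consequential.
- Major-axis regression is scale-dependent (days vs m s⁻¹); it matches
  the published choice but is not invariant to unit changes, unlike
  standardised major axis.
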