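# Methods

## Scope and data model

The package analyses gridded volume backscattering strength S_v
(dB re 1 m⁻¹) as depth × ping matrices with per-ping time and position, at
18 and 38 kHz, together with CTD station profiles of temperature (°C),
salinity (PSU), dissolved oxygen (µmol kg⁻¹), chlorophyll-a (µg m⁻³) and
PAR (µmol m⁻² s⁻¹). Depth is metres below the surface, positive downward;
depth axes hold bin centres of uniform half-open bins [z, z+Δz). Missing
samples are NaN and are excluded from every mean rather than treated as
zero or −∞, so dropout pings do not bias cell averages; counts of dropped
material are logged. Long-format CSV is the canonical interchange format
(modest grid sizes); netCDF3 via xarray's scipy engine is the bulk option.

## Preprocessing

All averaging is performed on linear intensity sv = 10^(S_v/10) — acoustic
intensities are additive — and converted back to dB. By Jensen's inequality
the dB of a linear mean is never below the plain dB mean; a property test
asserts this. Processing constants (defaults): surface exclusion 10 m;
echo-integration 0.1 nmi × 1 m, with along-track distance accumulated by
haversine on a spherical Earth (R = 6371 km; sub-metre error at cell
scale); extraction threshold −70 dB. The threshold comparison is inclusive
(a cell at exactly −70.0 dB is kept); the convention is configurable.
Echo-integration conserves total linear energy exactly by construction
(cell mean × sample count sums to the sample total), asserted to 1e−9
relative. Ping blocks are formed by flooring cumulative track distance at
the cell length; when ping spacing exceeds the cell length only populated
blocks become columns, and a stationary ship yields a single column with a
warning. No separate background-noise-removal stage is applied: the
synthetic floor sits 15 dB below the threshold, and real data are assumed
denoised upstream.

## Layer extraction and descriptors

SSLs are connected components of the thresholded grid under 4-connectivity
— the grid-resolution equivalent of filled isocontours at the threshold.
4- rather than 8-connectivity is chosen to keep vertically adjacent layers
separate; it is configurable. Components under `min_cells` (default 5,
configurable) are discarded as speckle with a logged count. Descriptors per
layer: minimum depth = top edge of the shallowest member bin, maximum depth
= bottom edge of the deepest, width = max − min (a single-cell layer has
width of one bin), length = along-track extent of member columns, mean S_v
= linear-domain mean over member cells. Layer dates follow a dawn-to-dawn
convention (06:00 UTC boundary): a diel cycle's post-midnight half keeps
the evening's date, so daily aggregates are not split at midnight.
Cross-frequency matching requires a shared column timebase (1 s tolerance)
and pairs layers greedily by descending Jaccard overlap of member cells,
accepting pairs at overlap ≥ 0.25 (a deliberately permissive default; at
0.5 only near-duplicate layers match, at 0.1 distinct adjacent layers begin
to pair).

## Diel classification and DVM

Solar altitude uses the NOAA low-accuracy ephemeris (fractional-year
Fourier series for declination and the equation of time). Spot checks
against an independently implemented Michalsky ephemeris agree within 0.3°;
near the zenith the altitude is maximally sensitive to the series' small
angular errors, which is immaterial against an 18° threshold. Refraction is
ignored. Day is altitude > +18°, night < −18°, twilight in between
(boundary values inclusive to twilight) and excluded from diel contrasts.
Day/night assignment of an integration column uses the column's mean time
and position.

Day and night mean profiles per 1 m bin are linear-domain means (a dB-domain
switch exists for comparison); Δ is night − day in dB. The weighted mean
depth of a column is WMD = Σ z_i·sv_i / Σ sv_i over non-missing cells, with
an optional threshold restriction. WMD is invariant to a constant dB offset.
For migration-amplitude estimates the threshold-restricted variant is used:
the unrestricted sum integrates the noise floor over the full water column,
which drags the night WMD toward mid-depth by an amount (∼14 m under the
default floor) unrelated to the migration itself. Cross-frequency
validation reports the Pearson r of paired WMD series and the per-frequency
day/night amplitude.

## Seascape classification

The cluster unit defaults to the calendar (dawn-to-dawn) day; per-layer
units are an option. Each unit's vector holds min depth, max depth, width
and mean S_v at both frequencies plus mean longitude and latitude (ten
descriptors). Daily aggregates are cell-count-weighted means over the day's
matched layer pairs, so a day's profile is determined by its major layers
rather than by near-threshold fragments that appear when a layer fades
through the threshold at dusk. Columns are z-scored; K-means
(k-means++ seeding, Lloyd iterations, best of 20 restarts, fixed seed
stream) is run for k in 2..8 (clipped to n−1) and k is chosen to maximise
mean silhouette width, ties toward the smallest k. Five-number summaries
with Tukey outlier counts (1.5 IQR) describe each cluster.

## Environmental driver models

Acoustic cells within 0.1 nmi (great circle) of a CTD station are pooled;
per-frequency S_v is the linear mean over above-threshold cells of the
matched columns, and each predictor is the station profile's mean over the
depth span of those cells (the model's environmental value should describe
the water the layer occupies; the profile is linearly interpolated over the
span). Stations with no match are excluded with a log (the cruise's
Caribbean gap is the archetype). Day and night records are both retained.

Collinearity screening flags predictor pairs with |r| ≥ 0.8; flags are
advisory and the exclusion list is configuration (default: turbidity, a
physical proxy collinear with chlorophyll-a, is dropped, while
temperature–oxygen is retained on ecological grounds).

The S_v models use identity link and Gaussian errors; temperature, salinity
and the region factor enter linearly, chlorophyll-a and oxygen as smooths,
and PAR as a smooth at 18 kHz but linearly at 38 kHz. Smooths are cubic
B-splines of basis dimension 10 with the penalty weight selected by
generalized cross-validation (statsmodels GLMGam); these basis choices are
declared defaults, not inferences. Continuous predictors are z-scored; the
response stays in dB. Reported: deviance explained
100·(1 − residual/null deviance) (clipped to [0, 100], since a heavily
penalized fit can formally exceed the null deviance), AIC, per-term Wald
p-values (joint tests for the region factor and each smooth's coefficient
block), and residual diagnostics (Shapiro–Wilk normality, Breusch–Pagan
heteroscedasticity against fitted values). Rank-deficient designs are
rejected naming the aliased terms. Refits with identical data and
configuration are bit-identical.

## Synthetic study conditions

The generator encodes three regional regimes:

- **AT** — one mesopelagic layer, daytime centre 450 m (σ = 30 m),
  migrating to 80 m at night; thermocline 100 m; mid-water oxygen minimum
  ~85 µmol kg⁻¹ near 350 m; surface chlorophyll ~0.5 µg m⁻³.
- **SA** — one thin layer (σ = 25 m), 430 m by day, 100 m by night; deep
  thermocline at 300 m; well-oxygenated to depth; oligotrophic
  (chlorophyll amplitude 0.08 µg m⁻³).
- **PA** — a persistent epipelagic layer at 60 m (no DVM), a day-only
  intermediate layer at 350 m (σ = 35 m, inside the 200–500 m band), and a
  deep migrator (520 m day → 80 m night); shallow thermocline/halocline
  (50/40 m), fresh surface (32.5 PSU), hypoxic OMZ reaching 20 µmol kg⁻¹.

Layer kinematics: centre depth = day_centre + (night_centre − day_centre) ·
σ(−altitude/6°), a logistic in solar altitude giving smooth crepuscular
transits; day-only/night-only layers fade with the same logistic.
Contributions of overlapping layers add in the linear domain on a −85 dB
noise floor; a per-ping Gaussian jitter (default sd 0.5 dB, a free
parameter — within-layer variance is not constrained by regional S_v
ranges) perturbs each layer's peak in dB. Peak amplitudes default to
threshold + 20/ln 10 ≈ −61.31 dB, which places the −70 dB isocontour
exactly at the ±2σ points of each Gaussian layer, so the extracted band
equals the layer's 2σ core band and the band-mean S_v falls at ≈ −63.5 dB.
CTD profiles are analytic (tanh thermocline/halocline, Gaussian OMZ dip and
chlorophyll maximum, exponential PAR) plus small seeded noise;
zero-noise runs reproduce the analytic forms exactly. Descriptor samples
for clustering are drawn from per-region normal regimes (PA: min ≈ 10 m,
widths ≈ 150/120 m, ≈ −63.5 dB; SA: widths ≈ 115/100 m, ≈ −67 dB; AT: max
≈ 400 m) around the regional position anchors.

What the generator does **not** emulate: frequency-dependent target
strength and resonance, multiple scattering, patchiness and internal-wave
displacement of layers, real noise spectra, or stochastic weather in the
hydrography. Passing recovery tests therefore demonstrates that the
pipeline's geometry, averaging and statistics are correct under the model's
assumptions — not that the model captures all features of survey data.

## Oracles and truth bands

Recovery tests compare extracted quantities to the generator's analytic
truth: the threshold-crossing band of floor + Gaussian bump (coincident
with ±2σ for the default peaks to well under one depth bin), extended by
the expected extreme-value widening from per-ping jitter over N columns
(≈ sd/√m · z_(1−1/N) in dB times the band's sensitivity, ~0.5 m under the
defaults — ignoring it fails a 2-bin tolerance on 200-column scenes). Where
layers overlap, the exact multi-layer crossing bands are computed on a fine
grid. Independent oracles in the test suite re-derive every delegated
primitive by a different route: flood fill vs connected-component
labelling, O(n²) silhouette vs scikit-learn, Michalsky vs NOAA solar
position, spherical law of cosines vs haversine, direct sums vs WMD and
Pearson, exhaustive partition enumeration vs K-means, and R mgcv vs the
statsmodels GAM on shared data.

## Problem sizes and determinism

Test and demo scenes are desk-scale by design: 2-hour extraction scenes
(≈200 integration columns), one full simulated day for diel analyses
(≈2400 columns, ping interval 20 s), 100 descriptor samples per region, and
GAM surfaces with n = 500. The pipeline demo simulates two days per region
(six per-day cluster units, enough rows for k up to 5; a single day per
region would leave silhouette selection no room above k = 2). A single run
seed fans out into per-stage seed streams, so stages are independently
reproducible and reruns are byte-identical (checksummed in the run
manifest).

## Known limitations

- The isocontour equivalent is component labelling at grid resolution;
  sub-cell contour geometry (marching squares) is not reproduced.
- Time-varied gain, absorption and sound-speed corrections are assumed done
  upstream; there is no vendor raw-file reader.
- Smooth-term p-values are Wald tests on penalized coefficient blocks and
  do not account for smoothing-parameter selection uncertainty.
- The pipeline GAM on fully synthetic scenes has little genuine S_v
  variance across regions (peaks are core-matched by design), so its
  deviance statistics exercise the machinery rather than demonstrate
  driver inference; the generate-and-recover surface is the meaningful GAM
  validation.
- No biomass conversion, school extraction, frequency-response
  classification, or eddy detection.
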