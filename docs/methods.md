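# Methods

## Scope and model

`canopylight` simulates spectrally resolved photon transport in small
virtual plant stands to compare direction-dependent (Phong) against
diffuse leaf optics.  Its parts are deliberately simple and separately
testable: a spectral grid with D65 photon weighting, a modified-Phong
leaf BRDF with fitting and sampling, a parametric plant/canopy
generator, a discretized sky, a forward Monte-Carlo tracer, and the
comparison statistics (η, MAPE, band shares, quantiles, paired t-tests).

### Spectral treatment

All quantities live on 30 contiguous 10 nm bins spanning 440–740 nm,
aggregated for analysis into blue [440,500), green [500,600), red
[600,700) and far-red [700,740] nm.  Every light source shares the CIE
D65 spectrum converted to photon units: the per-bin weight is
∫ S(λ)·λ dλ over the bin (the hc constant cancels on normalization),
computed by 1 nm trapezoids on the embedded 5 nm D65 table after linear
interpolation.  The embedded table removes any download dependency; a
60-bin refinement reproduces the 30-bin weights to better than 1e-3
relative.  Under this weighting green carries ≈34.5 % of daylight photon
flux, the single largest band share — which is why green also dominates
the simulated near-leaf photon flux.

### Leaf optics

The BRDF is the energy-normalized modified Phong model
f = kd/π + ks (n+2)/(2π) cosⁿα (reciprocal by construction).  The
directional–hemispherical reflectance is DHR(θi) = kd + ks·S(θi, n) with
S the cosine-weighted above-horizon lobe fraction.  S is evaluated by a
Gauss–Legendre rule in s = cosⁿ⁺¹α — which places nodes uniformly over
the lobe's energy for any shininess — times a 128-point uniform azimuth
rule; S(0,n) = 1 analytically, and the implementation is verified against
Monte-Carlo integration.  Transmission is Lambertian on the exit side
(no specular transmission), per the standard leaf-optics picture of
diffuse subsurface scattering.

Surface events use the probabilities (kd, ks·S(θi), τ, remainder); the
specular direction is drawn from the cosⁿ lobe, thinned by cos θo and
clipped to the horizon, i.e. exactly the distribution whose total mass is
ks·S — so sampled event frequencies reproduce the analytic DHR, and
below-horizon lobe mass is treated as absorbed.

Fitting minimizes squared BRDF residuals per bin and side under the
equality constraint DHR(40°) = ρ_ref (kd is eliminated, leaving a
bounded 2-parameter problem in (ks, log n) solved from six log-spaced
shininess starts).  40° is the calibration geometry at which the
hemispherical reference values are defined, and it anchors the
spectrally equivalent diffuse model ρ = DHR(40°).  The diffuse NRMSE is
reported for that same constrained constant (f = ρ_ref/π), making the
diffuse model a nested special case of the constrained Phong family —
hence NRMSE_phong ≤ NRMSE_diffuse is guaranteed, not incidental.  NRMSE
normalizes the RMSE by the mean measured BRDF of the bin (scale-free and
stable when specular peaks are sparse).

### Plant and canopy generator

The generator emulates a young greenhouse cucumber at the five-leaf
stage: stem height ~N(0.212 m, 0.03 m), five cordate laminae swept over
circular-arc midribs, leaf areas rising from order 1 to 4 with the
youngest (order 5) smallest, 144° spiral phyllotaxis with jitter, and a
per-plant one-sided leaf area targeting 0.185 m² (lognormal 8 % spread),
which puts a 3×3 grid at 0.2 m spacing at LAI 4.625 in expectation.
Lower leaves splay nearly horizontally on long radial petiole offsets
while upper leaves stand erect, keeping every lamina partly exposed to
the sky, as in real young plants.  Laminae are built at unit scale and
rescaled so uniform scaling hits the area target exactly (area grows as
the square of the scale factor).  Layouts: single, 3×3 (central plant:
the interior one) and 4×3 (central: the two interior plants) above a
black ground disk three times the canopy footprint.

The packaged optical fixture encodes the qualitative spectral physiology
of a cucumber leaf: blue/red strongly pigment-absorbed (diffuse
reflectance and transmittance low, so the flat ~0.05 wax-layer specular
lobe dominates directionality), green intermediate, far-red weakly
absorbed and near-diffuse; the abaxial side is brighter and more matte.
DHR(40°)+τ then orders far-red > green > red ≥ blue, and the specular
*fraction* ks/(kd+ks) is highest in blue and red.  The fixture is a
synthetic stand-in with plausible magnitudes, not a measurement.

What the generator does **not** emulate: real measured geometry (petiole
kinks, lamina lobes, serration), leaf-angle distributions measured on
plants, intra-leaf optical variation, and any species other than a
generic cucumber-like habit.  Passing tests therefore demonstrate
correctness of the transport and statistics machinery on realistic
magnitudes — not agreement with any particular measured plant.

### Sky, sun and scenarios

The diffuse sky is isotropic in radiance, discretized into 9 altitude ×
12 azimuth segments with one directed source per segment center; ring
weights follow the closed-form cosine-projected annulus integral
(sin²a₁ − sin²a₀), so the horizontal-plane irradiance of the discretized
sky equals E_diffuse exactly.  Direct sunlight is one directed source
whose *horizontal-plane* irradiance is q·E_global, which keeps
E_diffuse + E_direct = E_global exact at every altitude (the normal-plane
irradiance is E_direct/sin(altitude); consequently a horizontal
surface's interception is altitude-independent by construction, and the
sin(altitude) projection appears when specifying irradiance on the
normal plane instead).  The full sweep is q ∈ {0.1,…,1.0} × 4 azimuths ×
9 altitudes = 360 scenarios; the directionless q = 0 sky is available as
a separate baseline.  E_global defaults to 1000 µmol m⁻² s⁻¹ — all
reported statistics are scale-free, the round value only aids reading.

### Transport and tallies

Forward tracing from the sources (sensors are passive), with rays
emitted from a disk circumscribing the scene's bounding sphere and
allocated to sources in proportion to emitted power, so every ray starts
with the same total weight.  A ray carries all 30 bin weights.  At a
leaf hit, a pilot bin is drawn proportional to the current weight
vector; the scatter branch and direction are sampled from the pilot
bin's mixture kernel, and each bin's weight is updated by
w′_b = w_b · s_pilot · k_b(ωo)/k_pilot(ωo) (BRDF ratio for reflection,
τ ratio for transmission) — the mixture pdf makes all direction factors
cancel to exactly this ratio.  The difference w_b − w′_b is deposited as
absorbed at the surface.  This makes the ledger *telescoping*:
emitted = absorbed + ground + escaped + truncated holds to float
precision in every run, while all tallies stay unbiased; individual
deposits may be slightly negative, and disappear in aggregation.  A
one-bin-per-ray mode (each ray dedicated to a single bin, pilot = that
bin, deterministic survival weighting) serves as the validation switch;
both modes agree within Monte-Carlo error.  Stems reflect diffusely with
a broadband 0.15 reflectance and never transmit; the ground absorbs
everything; paths are capped at depth 50 with the residual weight
tallied as truncated; weight below 1e-13 of the initial is deposited in
place.  Disabling reflections terminates every path at its first
surface interaction after depositing the per-bin absorbed fraction.

Sensors are disks of radius 2.5 mm placed 5 mm along the local normal
from three lamina reference points (centroid, 1/3 and 2/3 along the
midrib) on both sides of every leaf of the central plants; every path
segment is tested against every sensor and one-sided crossings
accumulate the ray's weight, so sensor PPFD equals crossing flux over
disk area.  An up-facing sensor in an empty scene reads the configured
horizontal irradiance — this is the tracer's absolute calibration test.

### Statistics

η = 1 − E_without/E_with per leaf (or sensor band) from paired runs
sharing replicate seeds; values are reported unclamped, so Monte-Carlo
noise can make them slightly negative.  MAPE uses the diffuse run as
reference, grouped means with standard errors; zero-reference records
(fully shaded sensors) are dropped with a logged count, since the
relative error is undefined there.  Quantiles are type-7 (linear
interpolation).  Paired t-tests come from scipy; p-values are compared
only as bounds.  Common random numbers across {phong, diffuse} ×
{reflections on, off} passes of the same replicate reduce the variance
of all paired statistics; with ks = 0 the Phong and diffuse tracers
follow bitwise-identical paths, which is the null test.

## Problem sizes and defaults

Production-like runs use 2×10⁶ rays per replicate, 3 replicates, depth
50.  The pipeline's default scenario subset spans all ten direct
fractions at azimuth 0° and altitudes {10°, 50°, 90°} plus the q = 0
baseline; the acceptance script uses the coarser a-priori subset
q ∈ {0.2, 0.6, 1.0} × altitudes {10°, 50°, 90°} so a full paired study
(3 passes × 3 replicates × 9 scenarios) completes in about ten minutes
on one core.  Tests use 10⁵–10⁶ rays.  The tracer does roughly
0.3–0.7 million rays per second on one core depending on canopy size.

## Known limitations

* **Indirect light in dense generated stands.**  The generator is pinned
  to the published stand statistic (LAI 4.625 at 0.2 m spacing, i.e.
  ~4.6 leaf layers).  At that density the lower leaves of a 3×3 stand
  are deeply shaded, and their absorbed flux is dominated by scattered
  light: the computed per-order indirect proportion η reaches tens of
  percent, far above the few-percent peak reported for measured young
  plants — those values imply stands whose leaves are almost all
  directly exposed, which is geometrically incompatible with ~4.6
  closed leaf layers and leaf-level scattering albedos of 0.1–0.9.
  With the published LAI as the binding constraint, the large η of the
  synthetic stand is the physically expected outcome, not a transport
  error (the tracer's η is validated on open scenes); treat η results
  from the default dense stand as specific to that density.  The same
  density pushes the worst-case absorbed-flux MAPE between Phong and
  diffuse optics slightly above the level reported for measured plants
  (multiple scattering amplifies directional-reflectance effects, and
  denser stands see more of it).
* The Phong lobe is an empirical model; microfacet models would
  extrapolate better far from the 40° calibration angle.
* The isotropic sky has no circumsolar brightening or spectral
  sun/sky difference; scenarios are static (no sun path).
* Sensor geometry (disk radius) trades variance against locality at
  desk-scale ray budgets; absolute sensor readings are exact only in
  the empty-scene limit.
* No photosynthesis model is attached; absorbed flux is reported
  spectrally integrated or per band.
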