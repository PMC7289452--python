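# Methods

## Model overview

The package treats the light-dosimetry problem of intravesical PDT as
transport of photon packets from an isotropic point emitter through a
three-region medium: the bladder void (water, with optional added
scattering), a uniform-thickness wall, and an outer adipose layer thick
enough that essentially no light returns from beyond it. The clinically
relevant outputs are the irradiance distribution over the inner wall
surface (summarized as a dose surface histogram, DSH), virtual-sensor
estimates of its mean, and the depth to which the photodynamic
threshold criterion keeps treatment selective.

## Geometry

Shapes are implicit and star-shaped: a directional radius function
R(d̂) gives the inner surface, and the signed radial field
u(p) = |p| − R(p̂) indexes the layers (void u<0, wall 0≤u<t_w, adipose
t_w≤u<t_w+t_a). This guarantees by construction that every centroid ray
crosses the inner surface exactly once, gives exact ray–surface
intersection via 1-D root finding, and removes any meshing dependency;
surface meshes (legacy VTK, PLY) are exported for visualization only.
Lobulated shapes modulate the radius with bounded von-Mises–Fisher-type
bumps to emulate the non-spherical bladders seen on CT; the amplitude
bound (≤0.3 relative) keeps R positive and the surface well-resolved.

Linear dimensions are rescaled so the quadrature void volume
(V = ⅓∮R³dΩ, 128×256 Gauss–Legendre × uniform-azimuth grid) matches the
requested volume essentially exactly. Patch areas integrate the exact
star-shaped surface element R²/(d̂·n̂) dΩ over the spherical-Voronoi
cells of a Fibonacci direction lattice, so patch areas sum to the true
surface area and partition it without overlap.

Defaults: wall thickness 3 mm (a typical distended-bladder wall; the
per-patient value is not known, so it is configurable), adipose 12 mm
(~10 transport mean free paths of adipose tissue at 525 nm, i.e.
optically thick), void centroid at the origin, +z dome, −z neck,
−y dorsal. Units are mm internally; ml and cm appear only at the
interface.

## Optical properties

The built-in 525-nm set: wall μa 0.45, μs 14.6 mm⁻¹; adipose μa 0.149,
μs 6.9 mm⁻¹ (both g 0.9, n 1.37); void water μa 4.1×10⁻⁵,
μs 1.7×10⁻⁵ mm⁻¹, g 0.8, n 1.33. Derived quantities follow the usual
definitions: μs′ = μs(1−g), single-scattering albedo μs/(μs+μa) (0.970
for the wall; 0.992 at the μa 0.2 / μs 25 grid corner), and
μ_eff = √(3μa(μa+μs′)), which for the wall set gives an attenuation
length of 623 μm. The selectivity module takes μ_eff⁻¹ as an explicit
parameter (default 750 μm, the round-number green-light assumption)
rather than forcing the diffusion value of any property set, because
the two differ and both are legitimate modelling choices.

## Transport

Packet stepping samples exponential free paths s = −ln(1−ξ)/μt in the
current region. Boundary handling exploits the radial field: the
distance from a point to any u-level set is at least
|u − L| / sup|∇u|, and sup|∇u| ≤ 1 + L_R/ρ with L_R the angular
Lipschitz bound of R (estimated numerically at build time with a 1.25×
margin). Flights shorter than this bound provably cannot cross a
boundary and are taken in one step; near boundaries the flight falls
back to ≤0.05-mm marches with 40-step bisection refinement of the
crossing point (positional tolerance ≪ 1 nm). At the void–wall
interface the unpolarized Fresnel reflectance decides specular
reflection vs Snell refraction; the 1.33→1.37 step is simulated even
though its normal-incidence reflectance is only 2.2×10⁻⁴, and total
internal reflection on wall→void exit is included.

Absorption uses weight attenuation (w → w·albedo per scatter event).
Packets below a weight cutoff (default 10⁻⁴) deposit their residual
weight at the termination site instead of playing Russian roulette:
the bookkeeping identity absorbed + escaped = launched then holds
exactly on every run (the conservation check every pipeline run
enforces at 10⁻⁶), at the cost of a bias bounded by the cutoff itself,
far below Monte Carlo noise at the packet counts used. Each run uses
one seeded RNG stream in a single-threaded numba kernel; identical
(configuration, seed) pairs reproduce DoseMaps bitwise.

Surface irradiance is scored at every void→wall crossing as packet
weight per patch area (power incident per area, not cosine-weighted
radiance), before the Fresnel decision; this counts primary light and
all diffusely re-emitted light, which is exactly the integrating-sphere
build-up the cavity produces. The unscattered first incidence is scored
separately as the primary map. Wall absorption is tallied on 0.1-mm
depth shells in u; shell volumes use the sphere-equivalent inner area
scaled by ((r+u)/r)², adequate for decay-rate work. Per-run half-sample
maps (first vs second half of the packets) provide a Monte Carlo error
estimate for any derived statistic.

The Lambertian-wall mode replaces the wall with an ideal diffuse
reflector of reflectance ρ on a sphere; its total/primary scored power
is the geometric series 1/(1−ρ) and serves as the independent oracle
for the build-up physics (checked at 2% for ρ = 0.5 and 0.8).

## Dose surface histograms

The DSH is kept as an exact step function over patches (descending
irradiance vs cumulative area fraction); no smoothing, so results are
bit-reproducible. Percentiles are area-weighted. The heterogeneity
ratio is E(area fraction 0.05)/E(0.95) — "hottest 5% over coldest 5%" —
a deliberate operationalization, since qualitative factor-of-2/
factor-of-5 statements do not define a metric. DSH distance resamples
both curves linearly onto a common area-fraction grid and takes the
maximum vertical deviation relative to the reference mean; the default
"clinically relevant" flag threshold of 0.15 is a configuration value,
used for flagging only.

## Virtual sensors

All three implementations are normalized to read the true irradiance in
a uniform diffuse field — the virtual analogue of calibrating the
physical probes against an integrating cylinder. The normalization
divisor is computed numerically per sensor as its expected response to
a unit-irradiance Lambertian field over its patch neighborhood; when
the acceptance axis is parallel to the local normal this reduces to the
closed forms sin²θc for an NA cone (θc = asin(NA/n), Ω = 2π(1−cosθc) =
0.737 sr for NA 0.625 in water) and ½ for the cos² response (whose
hemisphere integral is 2π/3). Numeric calibration matters for the
angled-cut fibers: with a 25° tilt the closed forms mis-normalize by
~20%. An ideal-cosine response is available as a switch for sensitivity
analysis. Sensors snap to the nearest patch center and read from that
patch plus its angular neighbors to reduce variance; readings can come
from in-flight accumulation in the transport kernel or from an explicit
crossing log (the analytic test route).

Residual bias against the true mean is then a physical effect of field
anisotropy: a cut-end fiber calibrated diffuse but viewing a
primary-dominated field over-reads by up to 1/sin²θc ≈ 4.5×, a cos²
sensor by up to 2×, which is precisely why multi-sensor cages with wide
acceptance track the mean best across unknown tissue properties.

Monitoring subtracts the baseline offset (cystoscope light), zeroes
interruption intervals, classifies sensors as responding when their
median net irradiance exceeds 5% of the across-sensor median (the
protocol says only "responding sensors"; this is the package's
definition), and terminates at the exact trapezoid-segment crossing of
the target exposure. The ±9 J·cm⁻² tolerance quoted around the
90 J·cm⁻² clinical target is reported, not used for termination.

## Selectivity

Selectivity holds at depth d while φ(0)/φ(d) < SUR·T_normal/T_tumor.
Defaults: uptakes 77 and 0.4 mg·kg⁻¹ (SUR 192.5, reported as 192),
thresholds 2.121, 0.161, 0.128 ×10¹⁸ hν·cm⁻³ (tumor, urothelium,
muscle; tumor/urothelium ratio 13.17 ≈ 13.2), printed inverse ratio
0.0757 accepted alongside the recomputed 0.0759. Three depth modes are
kept distinct rather than reconciled: the 2.5-attenuation-length rule
of thumb (1.875 mm at 750 μm), the planar closed form ln(ratio)·μ_eff⁻¹
(2.01 mm at ratio 14.5), and a spherical mode that adds the
(R/(R+d))² cavity divergence and therefore always returns a depth at or
below the planar one. Simulated profiles take φ(0)/φ(d) ∝ A(0)/A(d)
from the scored wall absorption (valid within a uniform-μa region),
clipped to the monotone envelope against Monte Carlo noise.

## Synthetic data: what it emulates and what it does not

The geometry generator emulates the shapes and volumes of real CT-derived
bladders (40–250 ml, aspherical, lobulated) but not true patient
anatomy: no prostate indentation, no variable wall thickness, no neck
opening; layers are radial offsets. The trace generator emulates the
visible features of clinical recordings — per-sensor spread, baseline
offset from the cystoscope light, interruptions, drift, dead channels —
with white noise rather than physiological artifact structure. Passing
tests therefore demonstrate the correctness of the dosimetry machinery
and the direction and rough size of shape/placement/property effects,
not patient-level numbers.

## Problem sizes and numerical choices

Default desk-scale sizes: 10⁶ packets for oracle checks, 1.5–3×10⁵ for
DSH studies, 8×10⁴ per grid point for sensor comparisons, 200 patches.
At these sizes the patch-level Monte Carlo error is ~1–3% and every
behavioral effect asserted in the tests is resolved beyond the
half-sample error estimate. Ties in the DSH sort are kept adjacent
(stable sort); degenerate inputs (empty patch sets, zero-mean DSHs,
non-star geometries, sources outside the void, NA exceeding the medium
index) raise immediately with messages.

## A finding that contradicts the intuitive reading

Mild scattering in the void does not reduce the mean wall irradiance —
it raises it by a few percent. Scattering converts the near-normal
primary incidence into diffuse incidence, which increases the wall's
effective remission and hence the cavity build-up factor; since the
void itself absorbs almost nothing at low turbidity, the area-weighted
mean can only fall when void absorption becomes significant, which at
water absorption (4.1×10⁻⁵ mm⁻¹) requires metre-scale diffusion paths,
i.e. intralipid-grade turbidity (μs ≈ 85 mm⁻¹, μs′ ≈ 17): there the
mean drops by >10%. The DSH *shape* still degrades with turbidity
(hot/cold spots under source displacement), so the practical guidance —
keep the filling liquid clear, rinse when sensor readings drop — stands;
but a monotone decrease of the mean across the whole sweep is not a
property of this model, and the test asserting it documents that.

## Known limitations

Polarization, fluorescence, time resolution and wall-curvature-resolved
depth dosimetry are out of scope. The depth-shell volume model is
approximate for strongly aspheric shapes. The angled-cut fiber is
modelled as an NA cone tilted by the polish angle, not by refraction at
the polished facet. Sensor readings share the transport run's packets,
so sensor and true-mean estimates are correlated (conservative for
ratio comparisons).
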