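# Methods

`mrtsim` is a desk-scale model of a synchrotron microbeam radiation therapy
(MRT) beamline and its dosimetry chain. It mirrors the two-stage structure
used in production Monte Carlo models of such beamlines: **stage one**
produces photons at the source, filters and collimates them, and stores the
survivors in a phase-space file (PSF) at a fixed scoring plane; **stage two**
re-uses the PSF to compute dose in a vertically scanned phantom. The split
lets one beamline configuration serve many phantom studies.

## Coordinate system and geometry

X is the beam axis (depth into the phantom), Y horizontal (the microbeam
lateral direction), Z vertical (the scan direction). Default longitudinal
layout, metres from the source: beam-defining aperture (BDA) at 32.9 m,
conformal mask at 33.4 m, multi-slit collimator (MSC) and PSF scoring plane
at 33.4 m, phantom entrance face at 34.16 m. The exact paddle/aperture
stations of the real beamline are not public in one place; only ratios of
these distances enter the results (a projection magnification of
34.18/33.4 = 1.023 between the MSC and the 20 mm-depth plane).

## Source model

The wiggler (period 52 mm, 30 periods, peak field 2 or 3 T, ring
200.1 mA / 3.032 GeV) is treated as a sequence of bending-magnet sources.
The field B(z) = B_peak sin(2πz/λ) is sampled at 256 points per period and
each point radiates the universal Schwinger spectrum for its local field,

    d²N/(dE dz) ∝ |B(z)| · G1(E/E_c(B)) / E,
    G1(y) = y ∫_y^∞ K_{5/3}(x) dx,   E_c[keV] = 0.665 B[T] E_ring[GeV]².

G1 is evaluated by quadrature of the exponentially scaled Bessel function on
a log grid and interpolated through the smooth factor H(y) = e^y ∫ K_{5/3};
the table agrees with direct adaptive quadrature to better than 10⁻⁴.

Emission at horizontal angle θ comes from trajectory points where the
electron direction equals θ, i.e. where |B| = B_peak√(1-(θγ/K)²). Because
the fan subtended by the 30 mm BDA width (±0.456 mrad at 32.9 m) is narrow
compared with the wiggler deflection K/γ ≈ 2.5 mrad (3 T), the accepted
spectrum is close to the bending-magnet spectrum at the peak field; the pole
sum therefore carries a horizontal-acceptance mask selecting only trajectory
points radiating into the fan. Photons are produced only above 40 keV (the
soft component is fully absorbed by the filtration and would only cost
simulation time).

Sampled photons get vertical angles from a Gaussian with the standard
energy-dependent synchrotron opening σ_ψ(E) = (0.57/γ)(E_c/E)^0.43,
horizontal angles uniform across the fan, and linear polarisation in the
orbital plane. The real machine's intensity/energy roll-off with vertical
angle beyond the Gaussian core is not modelled; it mainly matters for the
tallest apertures. Vertical sampling can be restricted to the BDA's angular
window (a truncated Gaussian); the acceptance fraction is kept with the
batch so absolute rates survive the restriction, and the BDA cut itself
remains exact.

## Filtration and collimation

Filtration is spectrum-level Beer-Lambert transmission through the paddle
stack (0.45 mm graphene + 15 mm HD graphite at 45° + 2 mm Cu at 45° for 3 T;
the 2 T stack swaps the last Cu millimetre for 2 mm Al). A paddle at tilt t
presents thickness/ sin(t). Scatter from filters into the ~10⁻⁸ sr accepted
at 33.4 m is neglected. Mass attenuation coefficients for H, C, N, O, Al,
Cl, Ca, Cu and W are embedded on the standard compilation grid (10-300 keV)
and interpolated log-log; compounds use the mass-weighted mixture rule.
Graphene is carbon at graphite density (2.26 g/cm³), HD graphite 2.10 g/cm³;
argon in air is approximated by chlorine (1.3% by mass, negligible).

Collimation ray-traces photons from a point source through the BDA (30 mm ×
{0.532, 1.053, 2.014} mm), the conformal mask ({5, 10, 20} mm width; the
field *height* is produced by the scan, not the mask), and the MSC (50 μm
slits, 400 μm pitch, centred on the axis). Septa are fully absorbing by
default; a septa transmission fraction can be set for sensitivity studies
(the septa thickness itself is not modelled). Survivors are recorded at
33.4 m with position, direction, polarisation, energy and weight, and can be
stored as HDF5 or CSV.

For spectrum-level statistics (mode and mean energy at the PSF plane) the
BDA's vertical acceptance is folded into the spectrum analytically: a fixed
slit accepts a larger fraction of hard photons (whose vertical opening is
smaller), hardening the accepted spectrum by ~2 keV for the 2.014 mm BDA.
The filtered means are 93.6 keV (3 T) and 70.4 keV (2 T) with the default
angular model.

## Phantom Monte Carlo

The phantom is a homogeneous 140 × 100 × 100 mm slab of Gammex RMI457 solid
water (published elemental composition, 1.046 g/cm³; pure water is available
as a fallback material). The vertical scan is emulated exactly the way a
time-dependent parameterised geometry does it: primary i enters with the
phantom displaced by z_i = -H/2 + i·H/n for field height H.

Because the medium is homogeneous, free paths are sampled directly from the
total linear attenuation coefficient; no voxel-by-voxel stepping is needed.
Interactions are partitioned into photoelectric (all energy to an electron),
Compton (Klein-Nishina ratio sampled by the standard composition-rejection
method, electron direction from momentum conservation) and Rayleigh
(direction change only, Thomson angular law — the form-factor forward
peaking is ignored; the channel is a few percent of the total). The channel
split keeps the total exactly equal to the embedded tables: incoherent is
analytic Klein-Nishina × Z/A with a small binding correction, coherent uses
a per-gram water table, photoelectric is the remainder. Photons below 5 keV
(mean free path < 0.25 mm) deposit locally. Compton sampling is
unpolarised; the PSF carries polarisation for future use, but none of the
scored quantities (depth doses, Z-averaged Y-profiles) resolve azimuthal
scatter anisotropy.

Electrons deposit either **locally** (default for the broadbeam mesh, whose
2 × 2 × 5 mm voxels dwarf any electron range here) or along a straight
**CSDA-range track** with uniform linear energy deposition in 32 substeps
(default for the microbeam mesh, whose 10 μm lateral voxels are smaller than
the ~140 μm range of a 100 keV electron; this is what preserves the
microbeam penumbra). CSDA ranges use an embedded water table (per-mass
ranges are material-insensitive for low-Z media). Compton electron
directions are kinematic; photoelectrons are taken forward along the photon
— their channel is a few percent and their range sub-voxel at the dominant
energies, so the angular law is immaterial here.

Every history balances exactly: each keV entering the phantom ends either in
the in-phantom deposit ledger (scored in the mesh when inside it) or in the
escape ledger, so energy conservation holds to floating-point rounding per
history and per run. Identical (PSF, configuration, n, seed) reproduce the
grid bit for bit. A generation cap (64) force-deposits pathological
histories without breaking the ledger; in practice photons absorb or escape
within a handful of generations.

Scoring meshes: broadbeam 2 × 2 × 5 mm voxels over the full phantom
(approximating the reference ionisation chamber volume), microbeam
1 × 0.01 × 0.1 mm voxels over a 140 × 2 × 2 mm central column. Voxels are
half-open [lower, upper). Per-voxel statistical uncertainty comes either
from in-run batching (`n_batches`) or from aggregating independent-seed jobs
(per-voxel mean with 1.96·SD/√n, i.e. a 95% confidence limit on the mean).

## Absolute dose scale

Dose per voxel is D = (E_v/m_v) · (I_ring·t_exp/e)/n_e,sim · K_w, with the
beam-on time t = field height / scan speed (2 s for a 20 mm field at the
10 mm/s reference speed). The pipeline converts its photon bookkeeping into
the equivalent electron count n_e,sim through the absolute Schwinger rate of
the accepted fan, so the printed doses are on the natural scale of the
model. K_w is a calibration hook — the ratio of measured to simulated dose
under reference conditions (2 cm depth, 20 × 20 mm field, 10 mm/s, 1.053 mm
BDA) — and defaults to 1 because the analytical source's absolute flux is
trusted; `calibrate_kw` stores a measured ratio with its reference metadata.

## Film dosimetry

The film module reproduces a single-channel (green) microscope-scan
protocol: corrected pixel value P = |P_post − P_pre| after dividing both
scans by a mean-normalised white-field map (flat-field correction; division
rather than subtraction, the standard convention); dose via a fourth-order
polynomial valid over 0.25-64 Gy (evaluations mapping outside that range are
flagged unreliable — this is what makes sub-floor valley doses unusable);
ROI statistics over a 10 mm disc or square; and a GUM budget combining six
type A/B components in quadrature with coverage factor k = 2 (5.2% combined,
10.4% expanded). The blue channel is refused as unsuitable.

The synthetic film generator inverts the calibration curve numerically on
its monotone branch, adds the response to a uniform base level, applies an
illumination field and per-pixel multiplicative Gaussian "granularity"
noise (the real film's grain structure is only qualitatively known), and
quantises to 8 bits with round-half-away-from-zero. What passing tests show:
the analysis pipeline is self-consistent to within quantisation and the
stated budget. What they do not show: real EBT3 response, development-time
drift, or scanner artefacts beyond a smooth illumination field.

## Microbeam profile analysis

Lateral profiles average the dose over the mesh's Z extent per Y voxel
column (the film analysis does the same over its scan axis) and resample to
1 μm by linear interpolation. Peaks are local maxima above half the global
maximum separated by ≥200 μm, with positions refined by an intensity
centroid (sub-voxel precision; a raw argmax quantises the pitch to the
10 μm voxel grid). Peak dose averages a 30 μm window — the flat top of a
nominal 50 μm microbeam, clear of the penumbra; valley dose averages a
100 μm window centred between peaks. Both are averaged over the five
central microbeams. FWHM of the central peak is measured at half the apex
height above zero (the valley-referenced convention differs by <2% at these
peak/valley ratios and is switchable). The PVDR is peak over valley.

Note one genuinely physical effect: the MSC sits at 33.4 m and the analysis
plane at ~34.18 m, so the projected slit width and pitch are magnified by
2.3% (51.2 μm / 409.3 μm). Measured FWHM and pitch therefore sit slightly
above the nominal 50/400 μm, well inside a one-voxel (10 μm) tolerance.

## Problem sizes

The bundled acceptance computation transports a 12 × 10⁶-record microbeam
PSF (a typical production PSF size), of which ~1.2 × 10⁵ primaries cross
the 140 × 2 × 2 mm scoring mesh; the test suite's shared microbeam fixture
uses 6 × 10⁶ records and the pencil-beam attenuation checks use 5 × 10⁵
histories. These sizes resolve the 20 mm-depth profile with a few-percent
statistical error per profile point.

## Known limitations

- Point source: the finite electron-beam cross section (~100 μm scale) is
  not modelled; it would add ~1 μm-scale blur at the phantom.
- No vertical intensity/energy roll-off beyond the Gaussian opening model.
- Filter scatter, MSC septa thickness and mask scatter are not modelled.
- No bremsstrahlung from secondaries, no pair production (negligible below
  300 keV).
- Solid water uses water's per-gram coherent-scatter table and a water
  binding correction; the induced error in the channel split is at the
  percent level and does not move the totals.
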