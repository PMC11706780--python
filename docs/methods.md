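# Methods

`nanopearl` models unmyelinated CNS axons as pearls-on-a-string:
nanoscopic nonsynaptic varicosities (NSVs, ~180–400 nm wide) joined by
thin connectors (~50–220 nm wide), with the boundary between the two
defined by the inflection points of the axon outline.  The package has
four scientific layers — a synthetic-data generator, the EM-style
morphometry, an axisymmetric membrane-mechanics solver, and a
cable-equation conduction model — plus a pipeline layer that chains
them into seeded, reproducible runs.  This note records the models,
their assumptions, the numerical choices, and what the synthetic tests
do and do not establish about real data.

## The pearl backbone

All pearled geometries share one analytic family.  Each NSV is a C²
piecewise-cosine bump: a quarter-cosine inner half (peak diameter =
`nsv_width`) whose curvature changes sign exactly `nsv_length/2` from
the peak, joined C²-continuously to a quarter-sine tail of length one
quarter of the adjacent connector, which lands with zero slope on a
flat connector of diameter `connector_width`.  Consequences used
throughout:

* inflection points exist in closed form, so every synthetic profile
  carries exact ground-truth boundaries and dimensions;
* the central half of every connector is exactly flat, so the
  connector-width estimator (median over the central 50%) is unbiased
  by the taper;
* the same family parameterizes the cable model's trunk, so measured
  Table-style dimensions translate directly into simulated geometries.

A plain raised-cosine bump was rejected because its tails span twice
the inflection separation and would overlap neighbouring pearls for the
dissociated-culture dimensions (connector shorter than NSV).

## Synthetic data

`gen_pearl_profile` draws per-period dimensional jitter from
zero-truncated normals (only mean ± s.e.m. are reported for real
cohorts, so the per-axon s.d. default is s.e.m.·√n and user-overridable)
and adds white radius noise.  Default sample spacing is 5 nm, ≥10×
finer than the thinnest reported connector (52 nm).  `gen_sted_profile`
emulates a cytosolic-label STED line profile: axial intensity ∝ local
cross-section area, blurred by a Gaussian PSF of stated FWHM, sampled
at the pixel pitch, with optional Poisson noise.  `gen_serial_sections`
emulates 40-nm serial sectioning; the 3D length ground truth is the
Pythagorean combination of in-plane displacement and section span.

What the generator does *not* emulate: pixel-level EM texture, tracing
errors that are correlated along the outline, asymmetric/branched
varicosities, or real synaptic boutons.  Tests passing on this
generator therefore validate the measurement operators' geometry and
statistics, not robustness to raw-micrograph artefacts.

## Morphometry

`segment_profile` smooths the diameter function with a Gaussian kernel
(default s.d. 15 nm — well below the smallest connector, large enough
to suppress sampling noise), finds candidate NSVs as prominent local
maxima, and places each boundary at the inflection of the flank: the
extremum of the smoothed first derivative, which is the zero crossing
of the smoothed second derivative associated with that flank.  Where
the profile's curvature has a slope kink (the bump-to-flat join),
Gaussian smoothing displaces the inflection proportionally to the
smoothing scale; boundaries are therefore localized at scales σ and 2σ
and extrapolated linearly to σ → 0.  On noiseless synthetic chains this
recovers all four dimensions to well under one sample spacing, and it
is exact on pure cosine chains.

Under additive radius noise any direct inflection localizer acquires a
systematic inward bias (up to ~8% of NSV length at noise equal to 5% of
the connector radius): the varicosity side of the flank is much flatter
than the connector side, so the slope extremum wanders preferentially
into the NSV.  `cohort_dimension_means` removes this with a
parametric-bootstrap correction: a noise-matched template chain is
rebuilt at the measured cohort means, re-measured through the identical
pipeline (12 replicates, two fixed-point iterations), and the measured
template bias is subtracted.  Corrected cohort means land within ~2–3%
of truth at the noise levels above.  The correction assumes the
backbone family describes the data — true by construction here, an
approximation on real axons.

Other operators: NSV width = maximum diameter in the segment (the
"width" of a varicosity as drawn); FWHM lengths use peak-prominence
bases with linear interpolation; spacing periodicity reports the
fraction of center-to-center spacings within ±10% of the 190-nm
membrane-skeleton period; exclusion rules drop synaptic-flagged
varicosities and structures ≥ 1 µm wide without a presynaptic terminal;
summaries report mean ± s.e.m. (s.d./√n) per dimension.

## Membrane mechanics

The membrane is a thin elastic surface with energy

E = ∫ (κ/2)(2H − C₀)² dA + σA + E_osm(V),   E_osm = k_BT·[c_ext·V − n·ln V]

on axisymmetric shapes r(z) over a periodic axial domain.  Area
exchanges freely with implicit reservoirs at fixed tension σ; the
enclosed solute amount n is fixed, so the pressure difference
ΔP = k_BT(n/V − c_ext) responds to deformation (van 't Hoff).  Units:
nm, k_BT, k_BT/nm², k_BT/nm³.

**Effective osmotic coupling.**  At face value, 300 mOsm of ideal
osmotic stiffness exceeds every membrane stress by ~4 orders of
magnitude and simply pins the volume; a volume-pinned tube *deepens*
its pearling when tension rises, inverting the observed tension trend.
On shape-relaxation timescales a neuron is far from an ideal osmometer
(channels and transporters exchange solute), so the model scales the
van 't Hoff stiffness by an `osmotic_coupling` factor (default 0.003),
placing the osmotic modulus at the Laplace-pressure scale of a ~100-nm
tube.  Osmolarity inputs are therefore *milliosmolar equivalents*.
With this single choice, all three observed trends emerge from the
energy: raising external osmolarity deflates NSV width and length;
raising tension shrinks both with a smaller span than the osmolarity
series; rigidity (20–100 k_BT) has the most modest effect.

**Stability and the pearl period.**  A tense tube (σr₀²/κ ≫ 1) is
linearly unstable to peristaltic modulation — but only around the
*Laplace-equilibrated* cylinder (tension first deflates the tube until
ΔP carries the load); around the isotonic cylinder the pure cosine mode
is stable.  `pearling_stability` therefore equilibrates the uniform
mode per candidate wavelength before probing the modulation curvature
by symmetric second differences.  Energy curvature alone carries no
growth rate (it is most negative as k → 0), so the domain period is set
to √2 × the marginal wavelength, the classic fastest-growing-mode
relation for peristaltic instabilities.

**Relaxation.**  `relax_shape` is a monotone gradient flow of the
discretized energy (finite-difference gradient, so the descent is exact
for the discrete functional), with two accelerations that preserve
energy monotonicity through Armijo backtracking: the volume-stiff
uniform mode is relaxed by scalar Newton steps each iteration, and the
k⁴ bending stiffness is treated semi-implicitly by a Fourier-diagonal
preconditioner.  Termination: projected-gradient norm below `tol`
(default 1e-4 k_BT/nm; the finite-difference gradient noise floor is
~1e-5), pinch-off (min radius < `r_min`, flagged, partial state
returned), or `max_iter`.  Default grid: 96–128 nodes per period.

**Constant mean curvature.**  At equilibrium 2σH = ΔP − κ·(bending
terms); bending is *by construction* order-one within a neck boundary
layer of width ~√(κ/σ), because that is what saturates the instability
(the κ → 0 limit is pinch-off).  The unduloid property — H constant —
therefore holds on the tension/pressure-dominated surface outside that
layer: `cmc_deviation` reports the area-weighted relative spread of H
over r > 2.5·√(κ/σ), which is 2–5% across the pearling regimes tested.

## Conduction model

The generalized cable equation with Hodgkin–Huxley currents,

c_m ∂V/∂t = [1/(2πa√(1+a′²))] ∂x(πa²/R_i · ∂xV) − i_HH + i_stim,

keeps the true membrane-area factor √(1+a′²) in both the capacitive and
ionic terms (toggleable for comparison).  The model axon spans −90 µm
(AIS tip) to +300 µm; the AIS is a 500-nm cylinder tapering onto the
trunk over its last 5 µm, with Na, K and leak densities co-elevated 5×
(real initial segments are dense in Kv as well; co-scaling leaves the
resting state exactly uniform — elevating Na alone makes the AIS fire
spontaneously).  Stimulus: 40 µA/cm² for 1 ms over the proximal half of
the AIS.  Probes at −90, 0 and 277 µm; velocity = 277 µm divided by the
difference in quadratically-interpolated voltage time-to-peak between 0
and 277 µm (a half-maximum upstroke readout is kept as a cross-check
and agrees within 5%).

NaV layouts: uniform, or clustered every 190 nm (default cluster width
50 nm).  Each cluster represents one actin–spectrin ring and carries
the same channel complement regardless of local caliber, with the
trunk-integrated Na conductance matched exactly to the uniform layout.
K and leak stay uniform on the trunk.  Note that with conductance
conserved, any 190-nm redistribution is electrotonically homogenized —
the space constant is ~100 µm — so uniform and periodic layouts conduct
at the same speed on cylinders *and* on pearled geometries in this
model (measured differences < 0.05%).

**Numerics.**  Finite volumes on a uniform grid, default dx = 20 nm
(≥ 8 samples per connector, resolves the 190-nm layout); Crank–Nicolson
for the axial operator with the instantaneous ionic conductances
semi-implicit; gating advanced by an exact exponential step at frozen
voltage (staggered); default dt = 2 µs.  Halving dx and dt changes the
control velocity by < 1%.  Sealed ends; runs stop 0.5 ms after the
distal peak has passed.

**Calibration.**  The channel-density values of the original
parameterization are not available, so the model uses classic HH
kinetics, c_m = 1 µF/cm², R_i = 100 Ω·cm, and one calibrated constant:
`conductance_scale` (= 2.26) multiplying ḡ_Na and ḡ_K.  It is chosen
once, as the least-maximum-relative-error fit of the model's conduction
velocities to the six reference predictions for measured pearl
geometries (control, cholesterol-depleted, blebbistatin, and the
high-frequency-stimulation series), which places all six within ±10%
(max 8.5%).  A control-only anchor was rejected because the six
reference values are mutually inconsistent with any smooth
geometry-response model — fitting sensitivities exactly to four of them
implies a near-zero connector-width slope and a strong positive
NSV-length slope, contradicting the sweep behaviour — so balancing the
set is the better single-constant convention.  Geometry *sensitivities*
(the shape of every sweep, the width-optimum position, the ratio
surface) are invariant to this scale and to R_i, c_m and the kinetics
temperature factor; they are structural properties of the model class.

Two structural readouts deserve explicit caveats.  The velocity versus
NSV width curve is concave with its true maximum at ~271 nm for control
connector dimensions (the fitted Gaussian over the full 150–600 nm
sweep reports ~291 nm because the curve falls off asymmetrically).
And velocity rises monotonically with NSV length at fixed connector
dimensions, so the joint length × width sweep peaks at the long-length
edge of the observed range (length:width ≈ 2.6–3), not at an interior
ratio.

## Pipeline

Runs are described by one YAML configuration (per-stage blocks plus a
global seed and output directory).  Per-stage seeds are SHA-256-derived
from (global seed, stage name); identical configurations reproduce
identical output files bit-for-bit.  A JSON manifest records the config
hash, per-stage outputs, wall times and failures (a failing stage is
recorded without discarding completed outputs).

## Problem sizes used

Synthetic cohorts: 15–300 axons of 5–10 pearls.  Membrane relaxations:
96–192 nodes per period, converging in ~10³ iterations (seconds each).
Cable runs: ~19,500 nodes, 2-µs steps, a few seconds per geometry;
sweeps use 6–10 points per dimension and a 6 × 5 grid for the joint
length × width sweep.

## Known limitations

* Morphometry operates on extracted 1D radius profiles; it does not
  segment raw micrographs, and synaptic/axon exclusion flags are taken
  as given annotations.
* The membrane model is axisymmetric with homogeneous parameters; it
  produces periodic unduloid-like trains and cannot reproduce connector
  dimensions independently of the pearls (that would require spatially
  heterogeneous parameters, deliberately out of scope).
* The osmotic coupling factor is an effective, not measured, quantity.
* The conduction model is single-cable HH: no myelin, no stochastic
  gating, no extracellular field, and classic squid kinetics stand in
  for the unavailable native channel parameterization.
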