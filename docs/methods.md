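# Methods

`tetromap` simulates the optical side of cardiac optical mapping: how
photons injected into, and fluorescence emitted from, scattering myocardium
turn a transmembrane-voltage field V_m into the optical signal V_opt a
surface detector pixel records.  Its purpose is to quantify the distortion
that photon scattering — and in particular saline-filled, *non-scattering*
intramural vessel cavities, where diffusion-equation models do not apply —
imposes on optically recorded action potentials and shock responses.

## Photon transport model

Photon packets of weight W perform free-flight steps of length
`s = -ln(xi)/mu_t`, `mu_t = mu_a + mu_s` (xi uniform).  At the end of each
step the packet deposits `dW = W mu_a / mu_t` by absorption into the
tetrahedral element it occupies and scatters into a new direction drawn
from the Henyey–Greenstein phase function with anisotropy g
(`<cos theta> = g`), uniform azimuth.  Packets falling below the roulette
threshold survive with probability p and weight boost 1/p (unbiased).
Steps that cross element faces are chained through the face-adjacency
table: same-medium neighbours continue with the remaining step; faces
between different media trigger an unpolarized Fresnel
reflect-or-transmit decision with Snell refraction.  Non-scattering (bath)
elements are crossed in straight lines with the remaining step length and
weight frozen, resuming when (and if) the packet re-enters tissue.  This
bath free-flight is what lets the engine handle saline-filled cavities
exactly where photon-diffusion solvers break down.

The walk happens on unstructured tetrahedral meshes.  For each element,
inward face normals and plane offsets are precomputed; a step performs at
most four plane tests per traversed element.  Edge/vertex grazings that
leave no exit candidate nudge the packet 1e-7 mm forward and retry;
every face crossing is followed by the same nudge so a plane is never
re-intersected.  Kernels are numba-compiled; randomness is one
Mersenne-Twister stream per packet seeded by a splitmix64 hash of
(seed, packet index), making results reproducible and independent of
launch order.

### Optical parameters

Cardiac tissue at di-4-ANEPPS wavelengths (units mm^-1, coordinates mm):

| preset | mu_a | mu_s | g | use |
|---|---|---|---|---|
| illumination (488 nm) | 0.52 | 23.0 | 0.94 | excitation transport |
| emission (669 nm) | 0.10 | 21.8 | 0.96 | fluorescence transport |
| saline bath | 0 | 0 | — | straight-line transit |

Refractive indices are not constrained by any measurement we reproduce;
defaults are n_tissue = 1.40, n_bath = n_exterior = 1.33, but the engine
defaults to **index-matched mode** (no Fresnel events), and all headline
numbers are computed in that mode.  Fresnel physics is implemented and
unit-tested; enabling it is a config switch.

## Phantoms

Cuboid wedge phantoms stand in for MR-derived geometry: a 4 x 4 x 2 mm
(or 4 x 4 x 4 mm) tissue slab, optionally pierced by a cylindrical
saline-filled vessel cavity running along y (apex–base) — diameter 350 um
at 100 um below the epicardium, or 800 um at 200 um — inside a 100 um
saline shell on all faces.  Meshes are structured lattices of cubes split
into six tetrahedra (Kuhn subdivision; face-compatible, equal volumes),
default spacing h = 100 um.  Elements are tagged bath by
centroid-in-cylinder, so the cavity wall is stair-stepped; photon
transport has no curvature-sensitive term and the tagged volume matches
the analytic cylinder to ~1% at h = 100 um.  The lattice spacing is a
parameter (the reference meshes were ~50 um); h = 100 um keeps desk-scale
runs tractable and is validated by the volume and convergence checks in
the test suite.

## Pipeline

1. **Illumination** — packets launch from uniform points on every
   epicardial surface triangle along the inward normal (tilt optional) and
   are traced with the illumination preset.  Absorbed weight per element,
   divided by element volume, is the excitation photon density.  Absolute
   normalization is per launched packet; only normalized/fitted quantities
   are reported because the reference values' absolute scale is not
   recoverable.
2. **Fluorescent emission** — per-element source counts are a multinomial
   draw proportional to absorbed illumination weight (= density x volume;
   physically, absorbed excitation energy).  Packets start uniformly
   inside their source tetrahedron, isotropically directed, traced with
   the emission preset.  Every packet that leaves the domain is
   "detected" regardless of exit angle; its exit ray is intersected with
   the epicardial plane and its weight credited to each square pixel
   (half-open footprint) containing that point, binned by *origin
   element*.  The per-pixel origin histogram is the pixel's scattering
   (interrogation) volume; its total is the pixel signal.
3. **Signal synthesis** — V_opt(t) is the scattering-volume-weighted
   average of element-mean V_m (mean of the four node values; identical to
   centroid interpolation for linear elements).  A weighted *average* (not
   sum) keeps units and makes uniform fields fixed points; the
   ~10%-fractional-change presentation transform is an optional flag.
   Metrics: 10–90% upstroke duration with linear interpolation at the
   *first* upward crossing of each level (robust to humped morphologies),
   and shock-end polarization as percent of the paced AP amplitude.

## Synthetic V_m fields

Electrophysiology is *emulated*, not solved — no ionic model, no
monodomain/bidomain PDE.  What a green test establishes is therefore the
optics and the optics–V_m coupling, never electrophysiological dynamics.

* **Paced propagation**: a plane wave
  `V_m = rest + A sigma((t - x.d/cv)/tau)` with rest -85 mV, amplitude
  125 mV, tau = 1/ln 81 ms (so the electrical 10–90% upstroke is exactly
  1 ms), cv = 0.25 mm/ms transmural and 0.5 mm/ms circumferential.
  Transmural propagation runs toward the epicardium (d = +z).  The
  circumferential direction carries a 15 degree epicardiad tilt: in the
  reference simulations the rotational fiber architecture makes the
  circumferential wavefront concave, with intramural layers leading the
  surface, and the tilt reproduces that lead.  A perfectly
  surface-parallel plane wave carries no depth information and would make
  depth-weighted upstroke comparisons degenerate.
* **Shock snapshot**: exponential boundary layers
  `base + e_dep exp(-d_epi/lam) - e_hyp exp(-d_endo/lam)` plus, around a
  cavity, a dipolar virtual-electrode term
  `ve_amp (a/r) cos(phi) exp(-(r-a)/ve_lam)` with phi = 0 toward the
  epicardium (depolarized proximal side, hyperpolarized distal side).
  An optional depolarization ceiling `v_cap` (+40 mV in tests) encodes
  the saturation of the membrane's depolarized-side response;
  hyperpolarization is uncapped.  That asymmetry — a capped depolarized
  proximal lobe, an unbounded hyperpolarized distal lobe inside the
  scattering volume — is the mechanism by which optical polarization
  above a vessel *decreases* with shock strength while it increases over
  compact tissue.  The drive series used in tests is anchored to the
  magnitudes bidomain simulations report: e_dep = 100 + 1.5 D mV
  (epicardial depolarization beyond 100 mV already at moderate drives,
  then growing modestly), e_hyp = 8 D and ve_amp = 15 D mV (beyond
  +/-150 mV around the cavity at D = 20 V), lam = 0.3 mm (the ventricular
  space constant).  Only signs and orderings are claimed from this
  emulation, never absolute percentages.

## Analysis and validation

* **Penetration depth**: diffusion theory gives
  `delta = sqrt(D/mu_a)`, `D = 1/(3(mu_a + mu_s(1-g)))` — 0.581 mm at
  the illumination preset.  Monte Carlo delta is fitted by OLS on
  ln(density) vs depth along a thin central rod.  The fit window is the
  *linear region* of the log profile: z > 1 mm (above the sub-surface
  peak) and z < Lz/2 = 2 mm — in a finite 4 x 4 x 4 mm slab the decay
  steepens beyond ~2 mm as photons escape the lateral and far faces, a
  finite-slab deviation from the semi-infinite mono-exponential that the
  fit must exclude rather than average over.
* **Scattering-volume depth profiles** are normalized to their own
  maximal bin rather than the single maximal element: at desk-scale
  budgets (5e6 emission packets vs ~1e8 implied by the reference
  procedure) the element-wise max is an extreme-value statistic inflated
  ~2x by counting noise, which would bias every normalized value low; the
  bin-mean peak estimates the same converged quantity robustly.  The
  profile rod has a box cross-section: 1.5 lattice spacings across x
  (thin, resolving the cavity shadow like a line profile) by the pixel
  half-edge along y (the axis along which the phantom is geometrically
  invariant), chosen to suppress deep-bin counting noise without smearing
  lateral structure.  Readouts at a queried depth interpolate between bin
  centers, except across cavity gaps, where they snap to the nearest
  valid bin (a distal-edge reading must not mix in proximal-side values).
* **Independent oracle**: an MCML-style structured layered-slab Monte
  Carlo (analytic planar boundaries, no mesh, separately written sampling
  code) provides depth-binned fluence for cross-validation.  The
  tetrahedral engine must agree bin-by-bin (chi-squared over replicate
  means) and balance energy exactly (launched = absorbed + exited +
  roulette losses - roulette boosts).  Setting the cavity's medium to
  tissue with matched index must make the cavity optically invisible.

## Numerical choices

* roulette threshold 1e-4, survival 1/10 (standard MCML constants; the
  mechanism, not the constants, is prescribed by the reference method).
* geometric nudge 1e-7 mm; face-plane parallel tolerance 1e-12.
* point-in-element tie-break at shared faces: lowest element index.
* profile bin width 50 um; all acceptance readouts at 450/1000 um depth.
* xi = 0 in the step sampler is redrawn (ln 0 diverges); xi = 1 gives a
  zero step, which is harmless.

## Known limitations

* No fiber architecture; optics is isotropic per medium (as in the
  reference method) and electrophysiology is parametric.
* Desk-scale budgets leave a few-percent Monte Carlo scatter in deep
  normalized scattering-volume bins (worst for the large-vessel distal
  edge); quoted tolerances account for it.
* The faceted cavity wall is an approximation controlled only by lattice
  spacing; no curved-surface meshing.
* No detector optics (lens, numerical aperture, camera noise); detection
  accepts all exit angles, matching the reference analysis.
* Absolute photon-density and signal scales are per launched packet;
  only normalized or fitted quantities are comparable across runs.
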