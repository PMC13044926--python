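# Methods

This note records the models behind mxstrat, the defaults and why they were
chosen, what the synthetic fixtures do and do not emulate, and the numerical
conventions a maintainer needs to know.

## Conventions

One lab frame is used everywhere: beam along **+z** (crystal → detector),
ω rotation axis along **+x**, detector plane ⊥ z at distance D, coordinates
on the face in mm relative to the beam centre (default: face centre).
Goniostat composition, outermost first: ω about x, κ about an axis inclined
α to x in the x–y plane, φ about its rest direction x.  The crystal-to-lab
setting matrix of a sweep is R_κ·R_φ·U with U the orientation at all-zero
angles.  Rotation axes are unsigned throughout (a sweep about −v is a sweep
about v), which is why accessibility folds directions into a hemisphere.

Reciprocal vectors are normalized to λ = 1, so the Ewald sphere has unit
radius and the crossing condition for r₀ rotated about x is
r_z(ω) + |r₀|²/2 = 0 — a phase-shifted cosine with amplitude |r₀| sin X.
Reflections with X < θ (or X > 180° − θ) have no roots: the blind region.
The boundary X = θ counts as measurable (closed-set convention).  Partials
at sweep ends belong to the half-open interval [start, start + width).
Mosaicity and bandpass are zero: crossings are geometric events, which is
exactly what multiplicity arithmetic needs.

## Damage model and transmission

Intensity decay is exp(−β·D·d\*²/2) with β = 1.0 Å²/MGy — a B-factor
convention with B = β·D; β's units force the d\*²/2 arrangement.  The dose
budget inverts this at d\* = 1/d_target for the cutoff fraction (default
0.25, a heuristic: data whose high-resolution shell has lost three quarters
of its intensity are usually at the end of their useful life).

The dose conversion constant (MGy per photon/µm², default 2×10⁻¹⁰ at
12.4 keV) is an order-of-magnitude figure from published dose-rate tables;
every transmission recommendation depends on it only multiplicatively, and
all acceptance-style checks are proportionality checks, so its absolute
value is deliberately a configurable constant rather than a claim.

Effective flux density: Gaussian beams are replaced by top-hat beams of the
same total flux and FWHM widths; then F_eff = Φ/(bₓ·max(b_y, T)).  The
max() expresses two regimes continuously: a beam wider than the crystal
contributes its plain average density, while a narrower beam concentrates
all photons in the continuously irradiated slice bₓ×T — the weakest-signal
part of the crystal and therefore the right place to optimize transmission
for.  Consequence (verified in tests): a 16×2 µm beam at 4×10⁹ photons/s
and a 2×2 µm beam at 5×10⁸ are equivalent (both 2.08×10⁷ photons/s/µm² on a
12 µm crystal).

The voxel simulator is a deliberately small comparator: cubic crystal,
1 µm voxels, rotation about an axis through the centre, no photoelectron
escape, no beam divergence.  Reported intensity is Σ_v f(v,t)·decay_v,
normalized either at t = 0 (default; geometric corner features appear, as
they do in full dose simulations) or instantaneously (divides by
Σ_v f(v,t); isolates damage and shows the narrow-beam stair shape — fast
initial decay, near-flat plateaus, a step every 180° as the beam re-enters
previously irradiated material).  The fully bathed limit reproduces the
closed form to machine precision; the documented test tolerance is 1%.
The beam-equivalence test tolerances are 0.01 (weak dose, where the
effective-density approximation is exact) and 0.15 sup-norm at budget-level
dose: the two equivalent-by-formula beams genuinely drift apart by ~0.1 in
an explicit voxel computation once damage is deep, because their dose is
distributed differently along the rotation axis.

Only single-position dosing is modelled; "fresh section per sweep"
accounting for pseudo-helical collection is an extension hook, not
implemented.  Room-temperature damage is out of scope.

## Shadow model

The only obstruction modelled is the φ-axis mounting: an infinite cone of
half-angle A (default 19.84°, also used for the Smargon, whose main shadow
cone has a similar aperture) around −φ̂, apexed at the crystal.  Minor
κ-bracket shadows are ignored.  The model has the closed-form consequence
(90° − χ) − 2θ ≥ A for a shadow-free full turn, which reproduces the
detector limit table (χ_max = 90° − A − 2θ_max) and is cross-checked
against a numeric worst-ω search in tests.

`shadow_fraction` samples the face on a grid (default 256², documented
accuracy ~1/grid in each direction); `shadow_free_omega_range` returns the
widest ω window free of shadow for *every* κ in a set, while
`per_kappa_shadow_free_widths` gives the per-κ width.  The distinction
matters: the mount azimuth drifts by ~80° in ω as κ goes 90°→240°, so the
per-κ window keeps a roughly constant width (~217–252° for the largest
detector at 200 mm; ~176–184° at 100 mm) while the all-κ intersection is
much narrower (~158°/~101°).  A published figure quoting a single width for
a κ range can only mean the per-κ quantity, and the acceptance-style test
therefore compares the median per-κ width (tolerance ±15°, reflecting the
"about" nature of figure-derived values and the unspecified ω/κ zero
conventions).

## Symmetry

Operators for the 11 axial point groups are taken from the space-group
tables (gemmi) via representative symmorphic groups — P321 and P312 carry
the two arithmetic settings of 32, the stated reason arithmetic crystal
classes exist in the interface.  A brute-force closure of generators is the
independent oracle in tests.  Strategy symmetry selection follows "lowest
symmetry above monoclinic": among candidates with ≥3 proper operators,
rank by (operator count, crystal system, list position).  The
crystal-system component makes the pseudo-tetragonal ambiguity
{4, 422, 222, 2} resolve to 222 (orthorhombic before tetragonal at equal
operator count); remaining ties go to list order, and the choice is
deterministic.  Cubic groups are never chosen out of an ambiguity list by
this rule but are fully supported as direct inputs.

## Simulator and merging

Reflections are enumerated in an index box bounded by cell-edge/d_min and
cut to the d_min sphere.  Each sweep contributes up to two crossings per
turn per reflection (analytically; a brute-force sign-change scan is the
test oracle).  The Lorentz factor 1/(2 sin θ √(cos²θ − cos²X)) equals the
inverse crossing speed through the sphere; the tests verify this against a
finite-difference speed to 0.1% on 10⁴ reflections and its 1/sin 2θ
equatorial limit.

Detector hits are projected rays; the spot footprint is a 3-pixel disc
(configurable — no spot profile is modelled, so the 75% *area* criterion
stands in for a 75% intensity criterion), sampled at 25 deterministic
sunflower points; a reflection is gap-lost when less than 75% of the
footprint lies on active modules.  Module layouts are vendor-sheet data;
PILATUS4 layouts are not tracked and those detectors are modelled gapless.
On the PILATUS 6M the geometric face centre falls inside a vertical
inter-module gap; the beam centre still defaults to the face centre, as
offset centres are a beamline configuration, not a model property.

Merging maps observations to orbit representatives (lexicographic maximum
under the Laue group, with or without Friedel mates) entirely in integer
arithmetic.  Completeness denominators come from the full unique set at
d_min; "outside the blind region" restricts to unique reflections with at
least one member measurable in at least one sweep, and a unique reflection
is "cusp-free" when no member is blind — the population whose full-turn
multiplicity is exactly 2 × Laue order per 360°.  S/N enhancement is the
sum of Lorentz factors over retained observations of an orbit
(= multiplicity × mean L), binned equi-populated (default 10 bins).

## Strategies

Characterization: five wedges of 12 × 0.1° images, wedge starts equally
spaced over 0–180° inclusive — a spacing convention chosen here; the
endpoints give the most orthogonal view pair.

Advanced target orientations per point group are frozen package data
derived from polyhedron vertex coordinates (rhombicuboctahedron
(±1, ±1, ±(1+√2)); truncated cuboctahedron (±1, ±(1+√2), ±(1+2√2));
truncated octahedron, permutations of (0, ±1, ±2)), rotated so the
polyhedron symmetry contains the crystal symmetry frame (cube diagonal →
trigonal c axis, etc.).  Which vertices form the triplet/square is a
design choice made once to tile the sphere under the group action.  For
the high-multiplicity groups 6/422/622 no polyhedron fits and a documented
two-orientation compromise (polar 50°/70°, azimuth split across the
symmetry wedge) is used; point groups 1 and 2 get a four-orientation cap
spread limited by the goniostat range.

`fit_to_mounting` spins the target set about the principal symmetry axis
(2° grid) to minimize the maximum required χ, then solves (κ, φ) in closed
form (polar angle → κ through the half-angle formula, azimuth → φ).
Targets outside the mechanical χ limit (48° mini-κ; 45° Smargon) are
slerped onto the accessible-cone boundary — the documented
nearest-accessible fallback — with a warning.  Accessibility of a random
axis orientation is 1 − cos χ_max ≈ 33% at 48°, verified by Monte Carlo.

Sweep lengths: lowest-χ sweep first at 360° (scaling anchor); later sweeps
360° when the closed form says their full turn is shadow-free, else 192°
(40 × 4.8° batches, slightly over a half turn so the ends scale together)
started inside the per-κ shadow-free window.  Predicted maximum
multiplicity is 2 × Laue order × effective length/360° with 192° counted
as the 180° it was prolonged from; this reproduces the published 12-row
strategy table exactly and is cross-checked by crossing counts for three
groups.

Basic strategies reorient only when the mounted axis is within θ_max of a
unique symmetry axis (tilt by θ_max + 2° margin, the margin covering
orientation-matrix uncertainty); P1 always gets a second sweep tilted by
min(2θ_max + margin, χ_max) so the second cusp is covered.

## Phasing blocks

Minimum sweep lengths follow the Dauter summary: P1 180° + 2θ_max;
single-axis groups 360°/n aligned or 90° + θ_max orthogonal; other groups
360°/2n aligned on an even n-fold or 90° orthogonal.  For the monoclinic
orthogonal case the historical 180° + 2θ_max value is computable behind
`dauter_monoclinic=True`; the default follows the single-axis rule, and
the simulation tests show the 90° + θ_max sweep reaching ~98% anomalous
completeness outside the cusp *provided the ω start matches the symmetry
axis* — the start-angle sensitivity is real and large (91% → 98% over
starts).  Exact 100% holds only outside a volume somewhat larger than the
blind region, so simulation thresholds are set at 97.5% rather than 100%.
Aligning an evenfold axis with the rotation axis makes each reflection and
its Bijvoet comparison partner cross at identical ω (same image, same
scale) — asserted exactly in tests.

Cusp-fill sweeps are placed as far from the main rotation axis as the χ
limit allows (across the accessible cap); widths: 180° + 2θ_max (basic),
180° + 4θ_max (extended), or a pair of 2θ_max sweeps 180° apart.
Interleaving partitions a sweep into wedges acquired alternately at ω and
ω + 180°, crossed over an opaque wavelength list for MAD (no absorption-
edge physics).  The planner intentionally exposes blocks, not one canonical
plan per group: the right combination depends on the mounted orientation
and the beamline's recentring cost (~45 s per manual recentring is
reported, not optimized).

## Synthetic fixtures

`random_crystal` draws cell edges uniformly in 40–90 Å (angles 80–100°
triclinic, β 95–115° monoclinic, system constraints exact) and orientations
uniformly on SO(3), all from one seed.  Defaults T = 12 µm, s = 1.0 match
the reference beam-shape simulation geometry.  The fixtures emulate lattice
geometry and orientation statistics only — no structure factors, no
mosaicity, no absorption, no real detector noise — so passing tests
demonstrate geometric/statistical correctness of strategy computation, not
data quality on real crystals.

## Problem sizes and tolerances

Tests and the acceptance script run at the coarsest resolution that leaves
the checked property non-degenerate (multiplicity checks at 3–4 Å on 40–65 Å
cells, ~10³ unique; completeness checks at their stated resolutions, up to
~4×10⁵ crossings monoclinic at 1.22 Å); full runs take seconds on one CPU.
Numerical tie-breaks worth knowing: blind boundary classified measurable;
orbit representative = lexicographic maximum; ω intervals half-open;
footprint sampling 25 points (≈4% area quantization, well inside the 75%
criterion's slack); shadow grids 96–256 per axis with 1° ω steps.

## Known limitations

No intensity prediction or scaling model; no CAD-level collision detection
(χ is capped, nothing else); no multi-crystal or helical strategies; module
layouts for PILATUS4 unavailable; the ω/κ zero conventions of published
shadow maps are not recoverable, so only window widths are compared; the
select-symmetry tie-break beyond (operator count, system, list order) is a
package convention.
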