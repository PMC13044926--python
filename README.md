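# mxstrat

Strategy computation for rotation-method macromolecular crystallography
(MX) at synchrotron beamlines: radiation-dose budgeting, multi-axis
goniostat geometry with shadow prediction, a ray-tracing diffraction
simulator, and multi-sweep native and phasing strategy generation for the
11 axial point groups.

## The problem

A modern MX beamline can collect a complete data set in under a minute, so
the limiting questions are no longer "how do I finish before the crystal
dies" but "how do I spend a fixed dose budget to get complete, uniformly
redundant, well-scaled data".  Answering that requires combining several
models that this package implements as a library:

* **Damage and dose.**  At 100 K the intensity of a reflection at
  reciprocal resolution d\* decays with dose D as
  I/I₀ = exp(−β·D·d\*²/2), β = 1.0 Å²/MGy.  Inverting this at the target
  resolution for a configurable remaining-intensity cutoff (default 25%)
  gives a dose budget, and with the beam's *effective flux density* —
  Φ/(bₓ·max(b_y, T)) for a beam of top-hat (or FWHM) widths bₓ×b_y on a
  crystal of thickness T — a matching transmission.  A voxel simulator
  cross-checks the approximation on a rotating crystal.
* **Geometry.**  With the beam along +z and the rotation (ω) axis along
  +x, a centred detector of narrowest width w at distance D accepts
  2θ_max = arctan(w/2D).  The φ-axis mounting of a mini-κ goniostat
  shadows the detector inside a cone of half-angle A = 19.84° around the
  mount direction, so a full 360° sweep is shadow-free only when
  (90° − χ) − 2θ_max ≥ A, where χ is the tilt of the φ axis from ω
  (cos χ = cos²α + sin²α·cos κ, α = 24°).
* **Diffraction simulation.**  With reciprocal vectors normalized to
  λ = 1 the Ewald sphere has unit radius; a reflection crosses it when
  r_z(ω) + |r|²/2 = 0, which has 0 or 2 roots per turn.  Reflections with
  axis angle X < θ never cross (the blind "cusp"); those that do carry a
  Lorentz enhancement L = 1/(2 sin θ √(cos²θ − cos²X)).  Crossings are
  projected onto a module/gap detector layout and merged under the Laue
  group into completeness, multiplicity and S/N-enhancement statistics.
* **Strategies.**  Basic: one 360° sweep at low χ, reoriented only when
  the mounted axis sits within θ_max of a unique symmetry axis (two
  sweeps in P1).  Advanced: sweep orientations matched to vertices of
  semiregular polyhedra whose rotation group contains the point group
  (rhombicuboctahedron, truncated cuboctahedron, truncated octahedron),
  first sweep 360°, later sweeps 192° (= 40 batches of 4.8°) where
  shadowed.  Phasing: even-axis alignment, Dauter minimum sweep lengths,
  cusp-filling sweeps, ω/ω+180° interleaving and out-of-sequence splits.

## Worked example

```sh
python examples/simulate_sweep.py
```

```
P1, 180 deg to 1.93 A: 32328 predicted crossings
  completeness outside the blind region: 100.0%
  anomalous completeness: 89.2%

point group 2, 360 deg to 1.22 A: max multiplicity 8 (mean 7.45)
```

A half turn on a triclinic crystal measures every reflection outside the
cusp exactly once — the classic rotation-method guarantee — while ~11% of
the anomalous (Friedel-separate) set is still missing; a full turn on a
monoclinic crystal delivers two crossings for each of the four Laue mates
of a general reflection, hence maximum multiplicity 8, with the mean pulled
down by orbits grazing the cusp.  The other examples print the detector
limit table, the dose budget/transmission round trip (ending exactly at the
25% cutoff), native strategy plans (e.g. 360+192 = 552° for point group
622, maximum multiplicity 72) and the phasing building blocks.

Each example is a short narrative script over the public API
(`mxstrat.simulate_sweeps`, `mxstrat.merge_stats`,
`mxstrat.advanced_strategy`, ...); a thin `mxstrat` CLI wraps the same
functions (`mxstrat geometry table`, `mxstrat dose budget --resolution
1.93`, `mxstrat run --crystal xtal.yaml --mode advanced`).

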