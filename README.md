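# knottrp

Design geometry and unfolding biophysics of **torus-knotted tandem
repeat proteins** — for protein designers building knotted helical
repeat architectures and for biophysicists analyzing how such proteins
unfold at equilibrium, in stopped-flow kinetics, and under force.

Circular tandem repeat proteins close into a ring because the transform
between successive repeats is constrained to a pure rotation of 360°/N
about a common axis with zero axial translation. Viewing such a ring as
the trivial (p = 1, q = N) torus knot suggests a generalization: a
q-repeat protein whose inter-repeat rotation is

> **p · 360° / q** (rotation about the symmetry axis, translation = 0)

traces the (p, q) torus knot — p windings about the symmetry axis and q
windings about the torus tube. With gcd(p, q) = 1 the chain is single
and closed: (2, 3) gives a trefoil (3₁) three-repeat protein, (2, 5) a
pentafoil (5₁) five-repeat protein.

The package provides:

- **Backbone generation** (`backbone`): a parametric Cα-level generator —
  ideal α-helices placed along chords of the torus-knot centerline,
  circular-arc loops, propagation by the generating screw — plus a
  seeded design search over torus radii and helix placements scored by
  termini closure and steric clashes.
- **Knot verification** (`topology`): KMT chain simplification, exact
  integer Alexander polynomials from generic projections, handedness by
  the Gauss writhe integral (negative = left-handed), knot depth and
  knotted-core estimation by terminal truncation.
- **Rigid-body geometry** (`geometry`): Kabsch superposition and
  screw (rotation + axial translation) decomposition, the language the
  design constraint is stated in.
- **Equilibrium denaturation** (`equilibrium`): average emission
  wavelength, two-state and three-state (N ⇌ I ⇌ D) linear-extrapolation
  models, seeded multi-start fitting, ΔG(H₂O) = m·[den]₅₀.
- **Folding kinetics** (`kinetics`): single/double exponential fits,
  chevron limb regression and water-extrapolated half-lives,
  kinetic-partitioning amplitude fractions, interrupted-unfolding
  (double-jump) decay fits.
- **Force spectroscopy** (`smfs`): cantilever-bending correction, TVD
  denoising and rupture detection, Livadaru freely-rotating-chain
  contour-length transformation with 1 nm-bandwidth KDE, Bell-Evans
  rupture-force fits (constant-rate and exact ramp-survival
  likelihoods), and a seeded Monte-Carlo pulling simulator.
- **I/O and CLI** (`io`, `cli`): PDB/mmCIF reading (gemmi), CA-only PDB
  writing, FASTA, CSV tables, sequence masses, and a `knottrp` command
  with `design`, `knot`, `fit-eq`, `fit-kin`, `smfs` and `info`
  subcommands.

## Worked example

Design a trefoil-knotted three-repeat backbone (20- and 25-residue
helices joined by 3-residue loops), verify its topology, and measure
the realized inter-repeat screw:

```python
import knottrp as kt

model = kt.search_design(kt.SearchRanges(p=2, q=3),
                         kt.RepeatArchitecture(20, 3, 25, 3),
                         seed=1, budget=2000)
print(kt.score_model(model))
report = kt.classify_knot(model.chain, seed=1)
print(report.knot_type, report.handedness, report.determinant)
for screw in kt.verify_repeat_symmetry(model.chain, 3):
    print(round(screw.rotation_angle % 360, 6), abs(screw.axial_translation) < 1e-6)
kt.write_ca_pdb(model.chain, "trefoil.pdb")
```

prints

```
ModelScore(closure_distance=3.754243397137999, min_nonlocal_ca_distance=6.202842073743388, passed=True, closest_pair=(90, 94))
3_1 left 3
240.0 True
240.0 True
240.0 True
```

The 153-residue model closes its termini at 3.75 Å, has no non-local
Cα pair closer than 6.2 Å, classifies as a left-handed trefoil
(Alexander determinant |Δ(−1)| = 3), and every adjacent repeat pair is
related by a rotation of exactly 240° = 2·360°/3 with zero axial
translation — the torus-knot design constraint realized to machine
precision. The same call with `SearchRanges(p=2, q=5)` and architecture
`(24, 3, 22, 3)` produces a 5₁ pentafoil.

From a shell:

```
knottrp design --p 2 --q 3 --arch 20,3,25,3 --seed 1 --out trefoil.pdb
knottrp knot --pdb trefoil.pdb --depth
```

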