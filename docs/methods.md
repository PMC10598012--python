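# Methods

## Torus-knot repeat design geometry

A tandem repeat protein with q identical repeats closes into a ring
when the transform between successive repeats is a pure rotation about
a fixed axis. Factoring that transform into screw coordinates
(Chasles' theorem: rotation about an axis plus translation along it)
the constraint reads: rotation = p·360°/q, axial translation = 0. For
p = 1 the backbone is an unknotted toroidal ring; for p ≥ 2 the chain
passes p times about the symmetry axis and traces the (p, q) torus
knot, provided gcd(p, q) = 1 (otherwise the curve splits into
gcd(p, q) separate chains, impossible for a single polypeptide).

The generator here is parametric rather than fragment-based. The
centerline is the standard torus-knot curve

    C(u) = ((R + r·cos(qu + φ)) cos(pu), (R + r·cos(qu + φ)) sin(pu), r·sin(qu + φ)),

with major radius R, tube radius r and tube phase φ. This
parametrization has negative writhe and therefore yields left-handed
knots, matching the handedness of the designed trefoils this package
models. It is exactly equivariant under u → u + 2π/q composed with a
rotation of p·360°/q about z, so building one repeat on the first 1/q
of the curve and propagating it with the generating screw produces a
chain whose repeat symmetry holds to machine precision — the screw
tests measure 240.000000° (q = 3) and 144.000000° (q = 5) with axial
translations below 10⁻⁹ Å.

One repeat (helix1–loop1–helix2–loop2) is built as follows. Helix 1 is
an ideal α-helix (defaults: rise 1.5 Å/residue, twist 100°/residue, Cα
radius 2.3 Å) whose axis lies along the chord of the centerline from
u = 0 to the u at which the chord length equals (n_res − 1)·rise
(solved by bisection). Helix 2 is placed backwards from the end of the
repeat span: the trailing loop is allotted the parameter span matching
its contour budget at the local curve speed and the helix-2 chord is
solved toward earlier u. Loops are circular arcs joining fixed Cα
endpoints with a total arc length of 3.8 Å per virtual bond, bulged
along the outward tube normal; gaps longer than 3.9 Å per bond or
shorter than 75% of the nominal arc are rejected as infeasible (the
latter would compress consecutive Cα below physical spacing). Free
placement parameters are the two helix phase angles, a tilt of the
helix axes off their chords (documented range ±15°) and a radial
offset of the axes along the tube normal (±2 Å).

The design search samples (R, r, φ, placement) uniformly with a seeded
generator. The feasible R band is derived per sampled r from the
architecture: the repeat path length (helix chords plus loop arcs)
fixes the mean centerline speed √((pR)² + (qr)²). Models are scored by
termini closure |Cα_first − Cα_last| (accept ≤ 4.0 Å) and the minimum
non-local Cα–Cα distance (accept ≥ 3.8 Å). Non-local means cyclic
sequence separation > 3: the chain is circularly closed by
construction, so the first and last residues are treated as neighbours
rather than clashes (a deliberate refinement of a purely linear
separation rule, without which every well-closed model would sit
exactly at the clash boundary). Score-passing candidates are verified
topologically in descending score order and the first model whose knot
classification matches the intended torus-knot type is returned; the
search is deterministic given its seed. The default budget is 10,000
samples; tests and the acceptance script use smaller explicit budgets
(400–2,000) because a few hundred samples already yield dozens of
passing candidates for the reference architectures.

## Knot classification

Open chains are closed either directly (termini joined; appropriate
for designs with juxtaposed termini) or radially (termini extended
from the centroid to a sphere of 10× the chain extent and joined on
the sphere); `auto` picks direct when the termini are within 10 Å.
Closed polygons are simplified with Koniaris–Muthukumar–Taylor vertex
deletion: a vertex is removed when the triangle spanned with its
neighbours is pierced by no other segment. The piercing test is
conservative — ambiguous, near-degenerate configurations refuse the
deletion, which can only leave the polygon larger, never change its
topology. Coplanar cases (exactly planar polygons) get a 2-D
segment–triangle test so planar circles still reduce.

The Alexander polynomial is computed from a generic planar projection:
seeded random orientations are tried until no crossing falls near a
vertex, no two crossings coincide, and no segments overlap (after half
the attempts a 10⁻⁶-relative perturbation is added to break exact
degeneracies of ideal parametric curves). Arcs are cut at underpasses;
each crossing contributes the abelianized Wirtinger/Fox-calculus row
(positive crossing: t·x_in − x_out + (1 − t)·x_over). One row and one
column are deleted and the determinant is evaluated at integer t by
fraction-free Bareiss elimination in exact integer arithmetic, then
interpolated with rationals. Polynomials are canonicalized to lowest
degree 0 with positive leading coefficient and looked up in the table
{1: 0₁, t²−t+1: 3₁, t²−3t+1: 4₁, t⁴−t³+t²−t+1: 5₁, 2t²−3t+2: 5₂};
anything else is reported `unresolved` rather than guessed. The
closed-form torus polynomial Δ_{p,q}(t) = (t^{pq}−1)(t−1)/((t^p−1)(t^q−1))
serves as an independent oracle in the tests.

Handedness comes from the space writhe, evaluated exactly per segment
pair (Klenin–Langowski solid angles): negative writhe = left-handed,
the convention under which left-handed trefoils are −3₁. The Alexander
polynomial is mirror-invariant, so chirality cannot come from it; 4₁
is reported achiral.

Knot depth removes residues one at a time from a terminus, re-closes
and re-classifies; the depth is the largest number removable with the
knot type retained, a knot is shallow when nine or fewer residues
suffice at either terminus and deep otherwise, and the knotted core is
found by greedy bidirectional trimming. Note that for closed-curve
constructions re-closure can re-thread the knot, so depth reflects the
chain geometry plus the closure rule, exactly as in database practice.

## Equilibrium denaturation

Fluorescence spectra are summarized by the average emission wavelength
AEW = Σ F_i λ_i / Σ F_i over the acquired window. Denaturation curves
follow linear-extrapolation models: each transition has
K = exp(m([den] − [den]₅₀)/RT), and the observed signal is the
Boltzmann population average with linear native and denatured
baselines; the three-state model N ⇌ I ⇌ D uses the partition function
Z = 1 + K_IN + K_IN·K_DI and a constant intermediate signal α_I with
no baseline slope. Populations are evaluated in log space (softmax),
so extreme denaturant values cannot overflow. ΔG(H₂O) = m·[den]₅₀ is
an identity of the parameterization, and the total three-state
stability is the sum over both transitions. R = 1.987×10⁻³
kcal·mol⁻¹·K⁻¹ and T = 298.15 K by default.

Fitting is nonlinear least squares (trust-region reflective, m-values
bounded positive) with seeded multi-start initialization: baselines
from the curve ends, midpoints drawn over the sampled range, m-values
from 1–10 kcal·mol⁻¹·M⁻¹. The reported three-state fit orders its
midpoints. Standard errors are asymptotic (Jacobian); an AIC is
attached for model comparison but never applied automatically.
Synthetic-data defaults mirror the study conditions the package is
tested under: 41 points over 0–7.1 M denaturant, Gaussian noise of
0.2 nm on AEW curves, three-state truth with midpoints 5.3/6.6 M;
parameter-recovery tests require median midpoint errors below 0.1 M
over 50 seeds.

## Folding kinetics

Traces are fit to A₁e^(−k₁t)(+A₂e^(−k₂t)) + c with rates parameterized
in log space, seeded multi-start, phases ordered fast-first; points
before the instrument dead time (default 2 ms, a typical stopped-flow
value) are excluded. Chevron limbs are linear regressions of ln k on
[den]; the unfolding intercept extrapolates to water, where the
half-life is ln 2 / k_U(H₂O) (3.156×10⁷ s per year). A residual
Shapiro–Wilk diagnostic flags curvature when rollover points are
included in a limb; the rollover boundary is always a user parameter,
never auto-detected. Kinetic-partitioning amplitude fractions are
f_i = k_i/(k₁+k₂). Interrupted-unfolding series are fit to
k(t_age) = k_∞ + (k₀ − k_∞)e^(−λ·t_age) with a ±2·SE interval on λ.

The chevron simulator composes ln-linear folding and unfolding limbs;
an optional denaturant-insensitive sequential barrier combines with
the folding limb in series (1/k_eff = 1/k_pre + 1/k_f), reproducing
refolding rollover where the barrier becomes rate limiting — the
signature used to argue for denatured-state processes such as chain
unknotting. Mechanistic scheme selection is deliberately not encoded;
the module exposes the measurements (amplitude ratios, double-jump λ),
not a verdict.

## Force spectroscopy

The analysis pipeline assumes calibrated force-extension data.
Extensions are bending-corrected (x_corr = x − F/k). Baseline noise σ
is estimated from the last 5% of points; the force trace is denoised
by total variation (weight 2σ) and ruptures are drops exceeding 5σ
across a 20-sample window, with the event placed at the steepest
denoised decrease (TV clips peak corners, so the denoised maximum
itself is biased early); raw forces are reported at the detected
indices. Loading rates are force-vs-time slopes over the last 4 nm
before each peak.

Elasticity uses the freely-rotating-chain model with stiff element
b = 0.11 nm and bond angle γ = 41°, giving persistence length
l_p = b·cos(γ/2)/|ln cos γ| ≈ 0.37 nm. Three regimes are implemented:
the Gaussian response x/L = 2Fl_p/3kBT, the thermal-bending regime
x/L = 1 − √(kBT/4Fl_p), and the discrete high-force regime
x/L = 1 − kBT/2Fb. The first two share the standard worm-like
interpolation F·l_p/kBT = 1/(4(1−g)²) − 1/4 + g (tabulated densely and
inverted by monotone interpolation); the discrete branch takes over at
the crossover force kBT·l_p/b² ≈ 125 pN, anchored there so the spliced
response is exactly continuous and strictly increasing with x → L.
The response is intensive (x/L independent of L), so contour-length
transformation is a division: L = x_corr/(g(F)·s(F)), where s(F) is an
optional quantum-mechanical bond-stretching factor
s = 1 + F/K (+ c₂F²), default stretch modulus K = 28 nN, smooth,
non-decreasing, equal to 1 at zero force, and switchable off. The
exact published stretching coefficients are not reproducible from the
sources at hand, so the correction ships as a documented configurable
form with those contracts tested. Contour lengths from points above a
10 pN floor enter a Gaussian KDE whose bandwidth is fixed at 1 nm in
length units (not a data-scale multiple).

Rupture forces follow the Bell-Evans model, k(F) = k_off,0·e^(FΔx/kBT)
(kBT = 4.11 pN·nm at ~25 °C), with the most probable force
F* = (kBT/Δx)·ln(rΔx/k_off,0·kBT). Three fits are provided: a
maximum-likelihood fit of the constant-loading-rate density (the rate
being a single KDE-mode value or per-event values), a least-squares
fit to a normalized force histogram, and an exact ramp-survival
likelihood that uses each curve's recorded force-vs-time history,
log L = Σ[ln k(F_i) − ∫k(F(t))dt]. The last exists because
constant-velocity pulling of a polymer tether loads nonlinearly: the
loading rate varies about two-fold across the rupture-force band, the
rupture-force distribution is intrinsically broader than the
constant-rate density predicts (≈19 vs ≈13 pN standard deviation under
the simulated conditions), and only the survival likelihood is a
consistent estimator there. The end-to-end validation (simulate →
detect → transform → fit at 500 events, tether 70 nm, 1.6 µm/s,
100 pN/nm) requires the freed contour length within 1 nm, Δx within
10% and k_off,0 within a factor of two of the generating values.

The pulling simulator integrates the Bell hazard along the
deterministic ramp defined by the tether elasticity in series with the
cantilever, drawing rupture thresholds from an exponential
distribution; noise is added afterwards, so a zero-noise replica of
the same seed reproduces the identical ramp. Its default step (0.25 nm
of tip travel) resolves the force in ~1–3 pN increments for
realistic tether lengths; the step is configurable where a smoother
ramp is needed.

## What the synthetic data do and do not show

All fitting layers are validated by seeded simulation-and-recovery:
the generators produce data with the models' own functional forms plus
Gaussian (or multiplicative log-normal) noise at magnitudes typical of
the corresponding instruments. Passing these tests demonstrates that
the estimators are implemented correctly, are seeded-reproducible, and
recover known ground truth at realistic noise — not that the models
are adequate for any particular real protein: real denaturation
curves can have sloped intermediate baselines, real kinetics can mix
instrument artifacts into the fast phase, and real force curves
contain adhesion peaks, drift and multiple tethers that the simulator
deliberately omits (drift and voltage-level calibration are out of
scope; inputs are assumed calibrated).

## Numerical choices and limitations

- Rotation angles are reported in (−180°, 180°]; the screw axis is
  oriented so the axial translation is non-negative, with +z/+x/+y tie
  breaking for pure rotations. Identity-like rotations (< 10⁻⁸ °) have
  no axis and raise.
- Kabsch superposition rejects collinear or coincident point sets
  (rank < 2 after centering, tolerance 10⁻⁹ of the extent).
- KMT and crossing detection run on absolute tolerances scaled by the
  chain extent; the Alexander computation retries up to 64 seeded
  projections before declaring failure.
- The knot table covers 0₁, 3₁, 4₁, 5₁, 5₂ only; composite knots and
  anything else report `unresolved` with the polynomial attached.
- Depth scans are O(depth) full re-classifications and are the most
  expensive topology operation; they are intended for chains of a few
  hundred residues.
- Backbone loops are Cα-level circular arcs with no torsional realism;
  full-atom building and sequence design are out of scope.
- The Bell-Evans histogram mode requires a single loading rate; the
  trajectory likelihood requires stored curves, not just forces.
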