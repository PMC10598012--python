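"""Parametric generation of torus-knot tandem-repeat Cα backbones.

A (p, q) torus-knot repeat protein is a q-repeat chain whose inter-repeat
transform is the screw (rotation p·360°/q about the symmetry axis, zero
axial translation); after q repeats the chain has wound p times about the
axis and closes on itself, which requires gcd(p, q) = 1 for a single
chain.  The p = 1 case recovers the unknotted circular tandem repeat
limit (rotation 360°/q per repeat).

The generator here is parametric rather than fragment-based: each repeat
consists of two ideal α-helices whose axes follow chords of the torus-knot
centerline, joined by circular-arc loops at Cα spacing, and the full
backbone is produced by propagating the repeat with the generating screw.
The design search samples torus radii, phases and helix placements
(seeded), scores closure and steric clashes, and verifies the knot type
of accepted models against the intended (p, q) torus-knot type.

Defaults: ideal α-helix rise 1.5 Å/residue, twist 100°/residue, Cα radius
2.3 Å; closure cutoff 4.0 Å; non-local clash cutoff 3.8 Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist, squareform

from .geometry import RigidTransform, ScrewParameters, kabsch_superpose, screw_decompose
from .topology import classify_knot

__all__ = [
    "BackboneError",
    "TorusKnotSpec",
    "RepeatArchitecture",
    "HelixParams",
    "RepeatPlacement",
    "BackboneModel",
    "SearchRanges",
    "torus_knot_centerline",
    "build_repeat",
    "propagate_repeats",
    "score_model",
    "search_design",
    "verify_repeat_symmetry",
]

CA_SPACING = 3.8  # Å, target consecutive Cα distance
MAX_CA_SPACING = 3.9  # Å, loop feasibility limit per virtual bond


class BackboneError(ValueError):
    """Raised for invalid design specifications or infeasible geometry."""


@dataclass(frozen=True)
class TorusKnotSpec:
    """(p, q) torus-knot centerline specification.

    p : windings about the symmetry (z) axis.
    q : windings about the torus interior; equals the number of repeats.
    major_radius, minor_radius : torus radii R > r > 0 (Å).
    phase : tube phase offset (degrees).
    """

    p: int
    q: int
    major_radius: float
    minor_radius: float
    phase: float = 0.0

    def __post_init__(self):
        if self.p < 1 or self.q < 2:
            raise BackboneError("require p >= 1 and q >= 2")
        if math.gcd(self.p, self.q) != 1:
            raise BackboneError(
                f"(p={self.p}, q={self.q}) are not coprime: the curve would "
                "consist of more than one closed chain"
            )
        if not (self.major_radius > self.minor_radius > 0):
            raise BackboneError("require major_radius > minor_radius > 0")


@dataclass(frozen=True)
class RepeatArchitecture:
    """Residue counts of the helix-loop-helix-loop repeat unit."""

    helix1_len: int
    loop1_len: int
    helix2_len: int
    loop2_len: int

    def __post_init__(self):
        if self.helix1_len < 6 or self.helix2_len < 6:
            raise BackboneError("helix lengths must be >= 6 residues")
        if self.loop1_len < 1 or self.loop2_len < 1:
            raise BackboneError("loop lengths must be >= 1 residue")

    @property
    def repeat_len(self) -> int:
        return self.helix1_len + self.loop1_len + self.helix2_len + self.loop2_len


@dataclass(frozen=True)
class HelixParams:
    """Ideal α-helix Cα geometry."""

    rise_per_residue: float = 1.5  # Å
    twist_per_residue: float = 100.0  # degrees
    ca_radius: float = 2.3  # Å

    def __post_init__(self):
        if min(self.rise_per_residue, self.twist_per_residue, self.ca_radius) <= 0:
            raise BackboneError("helix parameters must be positive")


@dataclass(frozen=True)
class RepeatPlacement:
    """Free placement parameters of the two helices within a repeat.

    Documented ranges: phases unrestricted; tilt in [-15, 15] degrees
    (rotation of each helix axis away from its centerline chord, about the
    local tube normal); radial_offset in [-2, 2] Å (shift of each helix
    axis along the outward tube normal).
    """

    phase1_deg: float = 0.0
    phase2_deg: float = 0.0
    tilt_deg: float = 0.0
    radial_offset: float = 0.0

    def validate(self):
        if abs(self.tilt_deg) > 15.0 + 1e-9:
            raise BackboneError("tilt outside documented range [-15, 15] deg")
        if abs(self.radial_offset) > 2.0 + 1e-9:
            raise BackboneError("radial offset outside documented range [-2, 2] A")


@dataclass(frozen=True)
class BackboneModel:
    """A generated Cα backbone with its provenance and scores."""

    chain: np.ndarray
    spec: TorusKnotSpec
    architecture: RepeatArchitecture | None
    closure_distance: float
    min_nonlocal_ca_distance: float
    placement: RepeatPlacement | None = None

    def __post_init__(self):
        object.__setattr__(self, "chain", np.asarray(self.chain, dtype=float))


# ---------------------------------------------------------------------------
# Centerline
# ---------------------------------------------------------------------------


def _centerline_point(spec: TorusKnotSpec, u):
    """Point(s) on the torus-knot centerline at parameter u (radians)."""
    u = np.asarray(u, dtype=float)
    w = spec.q * u + np.radians(spec.phase)
    rho = spec.major_radius + spec.minor_radius * np.cos(w)
    return np.stack(
        [rho * np.cos(spec.p * u), rho * np.sin(spec.p * u),
         spec.minor_radius * np.sin(w)], axis=-1,
    )


def _tube_normal(spec: TorusKnotSpec, u):
    """Outward unit normal of the torus tube at parameter u (covariant)."""
    u = np.asarray(u, dtype=float)
    w = spec.q * u + np.radians(spec.phase)
    return np.stack(
        [np.cos(w) * np.cos(spec.p * u), np.cos(w) * np.sin(spec.p * u),
         np.sin(w)], axis=-1,
    )


def torus_knot_centerline(spec: TorusKnotSpec, n_points: int) -> np.ndarray:
    """Sample the closed (p, q) torus-knot curve at n_points parameters.

    Every sample lies exactly on the torus surface (distance minor_radius
    from the centerline circle of radius major_radius); the curve winds p
    times about z and q times about the tube.
    """
    if n_points < 3 * (spec.p + spec.q):
        raise BackboneError(
            f"n_points must be >= 3(p+q) = {3 * (spec.p + spec.q)}"
        )
    u = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return _centerline_point(spec, u)


# ---------------------------------------------------------------------------
# Repeat construction
# ---------------------------------------------------------------------------


def _rot_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K


def _ideal_helix(n: int, axis_dir: np.ndarray, center: np.ndarray,
                 ref_perp: np.ndarray, params: HelixParams,
                 phase_deg: float) -> np.ndarray:
    """n Cα positions of an ideal helix centered on the given axis."""
    d = axis_dir / np.linalg.norm(axis_dir)
    e1 = ref_perp - np.dot(ref_perp, d) * d
    ne1 = np.linalg.norm(e1)
    if ne1 < 1e-9:
        e1 = np.cross(d, [0.0, 0.0, 1.0])
        ne1 = np.linalg.norm(e1)
        if ne1 < 1e-9:
            e1 = np.cross(d, [1.0, 0.0, 0.0])
            ne1 = np.linalg.norm(e1)
    e1 /= ne1
    e2 = np.cross(d, e1)
    j = np.arange(n)
    axial = (j - (n - 1) / 2.0) * params.rise_per_residue
    theta = np.radians(phase_deg + j * params.twist_per_residue)
    return (center[None, :] + axial[:, None] * d[None, :]
            + params.ca_radius * (np.cos(theta)[:, None] * e1[None, :]
                                  + np.sin(theta)[:, None] * e2[None, :]))


def _arc_loop(P: np.ndarray, Q: np.ndarray, n_res: int, bulge_dir: np.ndarray,
              spacing: float = CA_SPACING) -> np.ndarray:
    """n_res loop Cα positions joining P to Q (exclusive) on a circular arc.

    The arc length is n_res+1 virtual bonds at ``spacing``; if the gap is
    longer than (n_res+1) * MAX_CA_SPACING the loop is infeasible.
    """
    g = float(np.linalg.norm(Q - P))
    nb = n_res + 1
    if g > nb * MAX_CA_SPACING:
        raise BackboneError(
            f"loop infeasible: gap {g:.2f} A > {nb} x {MAX_CA_SPACING} A"
        )
    s = nb * spacing
    if g < 0.75 * s:
        # A strongly bulged arc would compress the virtual bonds below
        # physical Cα spacing.
        raise BackboneError(
            f"loop infeasible: gap {g:.2f} A too short for a {n_res}-residue loop"
        )
    if g >= s - 1e-9:
        # Straight, slightly stretched placement.
        frac = (np.arange(1, nb) / nb)[:, None]
        return P[None, :] + frac * (Q - P)[None, :]
    # Circular arc with chord g and arc length s: solve sinc(theta/2) = g/s.
    f = lambda th: (math.sin(th / 2.0) / (th / 2.0)) - g / s
    theta = brentq(f, 1e-9, 2.0 * math.pi - 1e-9)
    rho = s / theta
    ex = (Q - P) / g
    ey = bulge_dir - np.dot(bulge_dir, ex) * ex
    ney = np.linalg.norm(ey)
    if ney < 1e-9:
        ey = np.cross(ex, [0.0, 0.0, 1.0])
        ney = np.linalg.norm(ey)
    ey /= ney
    mid = 0.5 * (P + Q)
    center = mid - rho * math.cos(theta / 2.0) * ey
    # P sits at angle 90° + θ/2, Q at 90° − θ/2 in the (ex, ey) frame; the
    # bulge apex (+ey) lies between them, so sweep directly from P to Q.
    a0 = math.atan2(float(np.dot(P - center, ey)), float(np.dot(P - center, ex)))
    a1 = a0 - theta
    ang = a0 + (a1 - a0) * np.arange(1, nb) / nb
    return (center[None, :] + rho * np.cos(ang)[:, None] * ex[None, :]
            + rho * np.sin(ang)[:, None] * ey[None, :])


def _helix_span(spec: TorusKnotSpec, u_start: float, chord_target: float) -> float:
    """Find u_end > u_start with |C(u_end) - C(u_start)| == chord_target."""
    A = _centerline_point(spec, u_start)

    def gap(du):
        return np.linalg.norm(_centerline_point(spec, u_start + du) - A) - chord_target

    hi = 2.0 * np.pi / spec.q
    # The chord must be reachable within one repeat's parameter span.
    if gap(hi) < 0:
        raise BackboneError("torus too small: helix chord does not fit in repeat")
    lo = 1e-6
    if gap(lo) > 0:
        raise BackboneError("degenerate helix chord request")
    return u_start + brentq(gap, lo, hi)


def build_repeat(architecture: RepeatArchitecture,
                 helix_params: HelixParams = HelixParams(),
                 placement: RepeatPlacement = RepeatPlacement(),
                 spec: TorusKnotSpec | None = None) -> np.ndarray:
    """Build one repeat of Cα coordinates along the torus-knot centerline.

    The two helices are ideal, their axes along (tilted) chords of the
    centerline; loops are circular-arc interpolations at ~3.8 Å Cα
    spacing.  The trailing loop connects to the screw-image of the first
    helix of the next repeat, so that propagation yields a continuous,
    closed chain.
    """
    if spec is None:
        raise BackboneError("build_repeat requires the torus-knot spec")
    placement.validate()
    arch, hp = architecture, helix_params
    du_repeat = 2.0 * np.pi / spec.q

    # Helix 1 chord.
    u0 = 0.0
    chord1 = (arch.helix1_len - 1) * hp.rise_per_residue
    u1 = _helix_span(spec, u0, chord1)
    A1, B1 = _centerline_point(spec, u0), _centerline_point(spec, u1)
    n_mid1 = _tube_normal(spec, 0.5 * (u0 + u1))
    d1 = B1 - A1
    if abs(placement.tilt_deg) > 1e-12:
        d1 = _rot_about(n_mid1, np.radians(placement.tilt_deg)) @ d1
    m1 = 0.5 * (A1 + B1) + placement.radial_offset * n_mid1
    helix1 = _ideal_helix(arch.helix1_len, d1, m1, n_mid1, hp,
                          placement.phase1_deg)

    # Helix 2 is placed backwards from the end of the repeat span: the
    # trailing loop gets the parameter span matching its contour budget at
    # the local curve speed, and the chord is solved toward earlier u.
    chord2 = (arch.helix2_len - 1) * hp.rise_per_residue
    eps_u = 1e-5
    speed_end = np.linalg.norm(
        _centerline_point(spec, du_repeat + eps_u) - _centerline_point(spec, du_repeat - eps_u)
    ) / (2 * eps_u)
    du_loop2 = 0.9 * CA_SPACING * (arch.loop2_len + 1) / speed_end
    u3 = du_repeat - du_loop2
    if u3 <= u1 + 1e-4:
        raise BackboneError("architecture does not fit the repeat span")
    B2 = _centerline_point(spec, u3)

    def back_gap(du):
        return np.linalg.norm(B2 - _centerline_point(spec, u3 - du)) - chord2

    if back_gap(u3 - u1 - 1e-5) < 0:
        raise BackboneError("torus too small: helix chord does not fit in repeat")
    du2 = brentq(back_gap, 1e-6, u3 - u1 - 1e-5)
    u2 = u3 - du2
    A2 = _centerline_point(spec, u2)
    n_mid2 = _tube_normal(spec, 0.5 * (u2 + u3))
    d2 = B2 - A2
    if abs(placement.tilt_deg) > 1e-12:
        d2 = _rot_about(n_mid2, -np.radians(placement.tilt_deg)) @ d2
    m2 = 0.5 * (A2 + B2) + placement.radial_offset * n_mid2
    helix2 = _ideal_helix(arch.helix2_len, d2, m2, n_mid2, hp,
                          placement.phase2_deg)

    # Loop 1 joins helix1 end to helix2 start.
    bulge1 = _tube_normal(spec, 0.5 * (u1 + u2))
    loop1 = _arc_loop(helix1[-1], helix2[0], arch.loop1_len, bulge1)

    # Loop 2 joins helix2 end to the next repeat's helix1 start.
    angle = 2.0 * np.pi * spec.p / spec.q
    Rz = _rot_about(np.array([0.0, 0.0, 1.0]), angle)
    next_h1_start = Rz @ helix1[0]
    bulge2 = _tube_normal(spec, 0.5 * (u3 + du_repeat))
    loop2 = _arc_loop(helix2[-1], next_h1_start, arch.loop2_len, bulge2)

    return np.vstack([helix1, loop1, helix2, loop2])


def propagate_repeats(repeat: np.ndarray, spec: TorusKnotSpec,
                      architecture: RepeatArchitecture | None = None,
                      placement: RepeatPlacement | None = None) -> BackboneModel:
    """Propagate one repeat by the generating screw into a full backbone.

    The screw is rotation p·360°/q about z with zero axial translation;
    its q-fold composition is the identity, closing the chain.
    """
    repeat = np.asarray(repeat, dtype=float)
    if repeat.ndim != 2 or repeat.shape[0] < 1:
        raise BackboneError("repeat must be a non-empty (n, 3) array")
    angle = 2.0 * np.pi * spec.p / spec.q
    Rz = _rot_about(np.array([0.0, 0.0, 1.0]), angle)
    blocks = [repeat]
    cur = repeat
    for _ in range(spec.q - 1):
        cur = cur @ Rz.T
        blocks.append(cur)
    chain = np.vstack(blocks)
    closure, min_nl, _ = _closure_and_clash(chain)
    return BackboneModel(chain, spec, architecture, closure, min_nl, placement)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


class ModelScore(NamedTuple):
    closure_distance: float
    min_nonlocal_ca_distance: float
    passed: bool
    closest_pair: tuple[int, int]


def _closure_and_clash(chain: np.ndarray, min_separation: int = 3):
    n = chain.shape[0]
    closure = float(np.linalg.norm(chain[0] - chain[-1]))
    D = squareform(pdist(chain))
    idx = np.arange(n)
    sep_lin = np.abs(idx[:, None] - idx[None, :])
    # The chain is circularly closed by construction: separation is cyclic,
    # so residues adjacent through the closure are local, not clashes.
    sep = np.minimum(sep_lin, n - sep_lin)
    mask = sep > min_separation
    if mask.any():
        Dm = np.where(mask, D, np.inf)
        i, j = np.unravel_index(int(np.argmin(Dm)), Dm.shape)
        min_nl = float(Dm[i, j])
        pair = (int(min(i, j)), int(max(i, j)))
    else:
        min_nl, pair = float("inf"), (0, 0)
    return closure, min_nl, pair


def score_model(model: BackboneModel, clash_cutoff: float = 3.8,
                closure_cutoff: float = 4.0) -> ModelScore:
    """Closure and clash scores with a pass/fail verdict.

    closure_distance: |Cα(first) − Cα(last)| (juxtaposed-termini criterion).
    min_nonlocal_ca_distance: minimum Cα–Cα distance over residue pairs
    with (cyclic) sequence separation > 3; ``closest_pair`` reports the
    offending residue pair when the clash check fails.
    """
    closure, min_nl, pair = _closure_and_clash(model.chain)
    ok = closure <= closure_cutoff and min_nl >= clash_cutoff
    return ModelScore(closure, min_nl, ok, pair)


# ---------------------------------------------------------------------------
# Design search
# ---------------------------------------------------------------------------

_TORUS_TYPE = {(2, 3): "3_1", (2, 5): "5_1", (2, 7): "7_1"}


def expected_knot_type(p: int, q: int) -> str:
    """Knot type of the (p, q) torus knot within the supported table."""
    if p == 1 or q == 1:
        return "0_1"
    return _TORUS_TYPE.get((min(p, q), max(p, q)), "unresolved")


@dataclass(frozen=True)
class SearchRanges:
    """Sampling ranges for the seeded design search.

    When radii ranges are omitted they are derived from the architecture:
    the repeat's path length (helix chords plus loop arcs) fixes the curve
    speed, hence a feasible (R, r) band.
    """

    p: int = 2
    q: int = 3
    major_radius: tuple[float, float] | None = None
    minor_radius: tuple[float, float] = (6.0, 12.0)
    phase: tuple[float, float] = (0.0, 360.0)
    phase1: tuple[float, float] = (0.0, 360.0)
    phase2: tuple[float, float] = (0.0, 360.0)
    tilt: tuple[float, float] = (-8.0, 8.0)
    radial_offset: tuple[float, float] = (-1.0, 1.0)

    def curve_speed(self, arch: RepeatArchitecture, hp: HelixParams) -> float:
        """Required centerline speed |dC/du| for the architecture's path."""
        chords = ((arch.helix1_len - 1) + (arch.helix2_len - 1)) * hp.rise_per_residue
        loops = CA_SPACING * (arch.loop1_len + 1 + arch.loop2_len + 1)
        return self.q * (chords + loops) / (2.0 * np.pi)

    def major_radius_band(self, r: float, arch: RepeatArchitecture,
                          hp: HelixParams) -> tuple[float, float]:
        """Feasible major-radius band for a given minor radius.

        The mean centerline speed sqrt((pR)^2 + (qr)^2) must match the
        repeat path length; R is sampled around that solution.
        """
        if self.major_radius is not None:
            return self.major_radius
        speed = self.curve_speed(arch, hp)
        R_est_sq = (speed**2 - (self.q * r) ** 2) / self.p**2
        R_est = math.sqrt(max(R_est_sq, (1.35 * r) ** 2))
        return (max(0.95 * R_est, 1.25 * r), max(1.25 * R_est, 1.3 * r))


def search_design(ranges: SearchRanges, architecture: RepeatArchitecture,
                  seed: int, helix_params: HelixParams = HelixParams(),
                  budget: int = 10_000, clash_cutoff: float = 3.8,
                  closure_cutoff: float = 4.0,
                  max_verify: int = 50) -> BackboneModel:
    """Seeded random search for a valid knotted backbone.

    Samples (R, r, phase, placement) uniformly from the ranges, keeps
    models passing the closure/clash score, and returns the best-scoring
    model whose knot classification matches the intended (p, q) torus-knot
    type.  Deterministic for a given seed.
    """
    target = expected_knot_type(ranges.p, ranges.q)
    rng = np.random.default_rng(seed)
    candidates = []
    best_diag = (float("inf"), -float("inf"))
    for _ in range(budget):
        r = rng.uniform(*ranges.minor_radius)
        R = rng.uniform(*ranges.major_radius_band(r, architecture, helix_params))
        try:
            spec = TorusKnotSpec(ranges.p, ranges.q, R, r, rng.uniform(*ranges.phase))
            placement = RepeatPlacement(
                rng.uniform(*ranges.phase1), rng.uniform(*ranges.phase2),
                rng.uniform(*ranges.tilt), rng.uniform(*ranges.radial_offset),
            )
            repeat = build_repeat(architecture, helix_params, placement, spec)
            model = propagate_repeats(repeat, spec, architecture, placement)
        except BackboneError:
            continue
        sc = score_model(model, clash_cutoff, closure_cutoff)
        best_diag = min(best_diag, (sc.closure_distance, -sc.min_nonlocal_ca_distance))
        if sc.passed:
            candidates.append((sc.min_nonlocal_ca_distance, -sc.closure_distance, model))
    if not candidates:
        raise BackboneError(
            "design search exhausted its budget without a passing model; "
            f"best closure/min-distance seen: {best_diag[0]:.2f} A / "
            f"{-best_diag[1]:.2f} A"
        )
    candidates.sort(key=lambda c: (-c[0], -c[1]))
    for k, (_, _, model) in enumerate(candidates[:max_verify]):
        report = classify_knot(model.chain, seed=seed)
        if report.knot_type == target:
            return model
    raise BackboneError(
        f"no score-passing model classified as {target} among the top "
        f"{min(max_verify, len(candidates))} candidates"
    )


def verify_repeat_symmetry(chain, q: int) -> list[ScrewParameters]:
    """Screw parameters of each adjacent repeat-pair superposition.

    Splits the chain into q equal blocks and, for each cyclically adjacent
    pair, superposes block i onto block i+1 and decomposes the transform.
    Deviations of the rotation angle from p·360°/q or of the axial
    translation from zero flag broken repeat symmetry, as observed in
    misfolded crystal structures with symmetric sequences.
    """
    chain = np.asarray(chain, dtype=float)
    if q < 1:
        raise BackboneError("q must be >= 1")
    if q == 1:
        return []
    if chain.shape[0] % q != 0:
        raise BackboneError(f"chain length {chain.shape[0]} not divisible by q={q}")
    L = chain.shape[0] // q
    blocks = [chain[i * L:(i + 1) * L] for i in range(q)]
    out = []
    for i in range(q):
        t, _ = kabsch_superpose(blocks[i], blocks[(i + 1) % q])
        out.append(screw_decompose(t))
    return out
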