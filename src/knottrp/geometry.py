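"""Rigid-body geometry: superposition and screw-axis decomposition.

Tandem-repeat closure constraints are expressed as a screw motion: the
transform carrying repeat *i* onto repeat *i+1* is factored into a rotation
about an axis plus a translation parallel to that axis (Chasles' theorem).
This module provides the optimal (least-squares) superposition of point
sets, the screw factorization of a rigid transform, and the inverse
composition used to verify it.

Conventions
-----------
* Coordinates are Å, stored as ``(n, 3)`` float arrays.
* ``rotation_angle`` is reported in degrees in ``(-180, 180]``.
* The screw axis is oriented so that the axial translation is >= 0; for a
  pure rotation (zero translation) the axis is oriented toward positive z,
  breaking remaining ties toward positive x, then positive y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GeometryError",
    "RigidTransform",
    "ScrewParameters",
    "kabsch_superpose",
    "screw_decompose",
    "screw_compose",
    "apply_transform",
]

#: Orthonormality tolerance for rotation matrices.
ROTATION_TOL = 1e-9
#: Rotations smaller than this (degrees) have no defined axis.
MIN_AXIS_ANGLE_DEG = 1e-8


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


def _as_points(pts, min_len: int = 1) -> np.ndarray:
    arr = np.asarray(pts, dtype=float)
    if arr.ndim == 1 and arr.size == 3:
        arr = arr.reshape(1, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise GeometryError(f"expected an (n, 3) point array, got shape {arr.shape}")
    if arr.shape[0] < min_len:
        raise GeometryError(f"need at least {min_len} points, got {arr.shape[0]}")
    if not np.isfinite(arr).all():
        raise GeometryError("points contain non-finite coordinates")
    return arr


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise GeometryError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation matrix has determinant -1 (improper)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_z(cls, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        R = Rotation.from_euler("z", angle_deg, degrees=True).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def __call__(self, pts) -> np.ndarray:
        return apply_transform(self, pts)


@dataclass(frozen=True)
class ScrewParameters:
    """Screw factorization of a rigid transform.

    Attributes
    ----------
    axis_direction : unit vector along the screw axis.
    axis_point : a point on the axis (Å); chosen perpendicular to the
        axis direction from the origin (canonical representative).
    rotation_angle : degrees, in (-180, 180].
    axial_translation : Å, translation along ``axis_direction`` (>= 0 by
        the axis-orientation convention whenever it is nonzero).
    """

    axis_direction: np.ndarray
    axis_point: np.ndarray
    rotation_angle: float
    axial_translation: float

    def __post_init__(self):
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise GeometryError("axis_direction must be a unit vector")
        object.__setattr__(self, "axis_direction", d)
        object.__setattr__(
            self, "axis_point", np.asarray(self.axis_point, dtype=float).reshape(3)
        )


def apply_transform(t: RigidTransform, pts) -> np.ndarray:
    """Apply a rigid transform to one point or an (n, 3) point set."""
    arr = _as_points(pts)
    return arr @ t.rotation.T + t.translation


def kabsch_superpose(mobile, target) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns the rigid transform minimizing the RMSD between the transformed
    mobile set and the target, and the residual RMSD (Å).  Uses the SVD
    (Kabsch) solution with the determinant correction for proper rotations.

    Raises
    ------
    GeometryError
        If lengths differ, fewer than 3 points are given, or the point
        sets are degenerate (all collinear or coincident).
    """
    P = _as_points(mobile, min_len=3)
    Q = _as_points(target, min_len=3)
    if P.shape != Q.shape:
        raise GeometryError(
            f"point sets differ in length: {P.shape[0]} vs {Q.shape[0]}"
        )
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    scale = max(np.abs(P0).max(), np.abs(Q0).max(), 1.0)
    # Degeneracy: rank < 2 means the rotation about the common line is free.
    for name, X in (("mobile", P0), ("target", Q0)):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-9 * scale:
            raise GeometryError(f"{name} points are collinear or coincident")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    diff = apply_transform(transform, P) - Q
    rmsd = float(np.sqrt((diff**2).sum() / P.shape[0]))
    return transform, rmsd


def _orient_axis(axis: np.ndarray, angle_deg: float, h: float, tol: float = 1e-9):
    """Apply the axis-sign convention; returns (axis, angle, h)."""
    flip = False
    if h < -tol:
        flip = True
    elif abs(h) <= tol:
        # Pure rotation: orient toward +z, then +x, then +y.
        if axis[2] < -tol:
            flip = True
        elif abs(axis[2]) <= tol:
            if axis[0] < -tol:
                flip = True
            elif abs(axis[0]) <= tol and axis[1] < 0:
                flip = True
    if flip:
        axis = -axis
        h = -h
        # 180 deg is its own inverse representative; keep it positive.
        if abs(abs(angle_deg) - 180.0) > tol:
            angle_deg = -angle_deg
    return axis, angle_deg, h


def screw_decompose(t: RigidTransform) -> ScrewParameters:
    """Factor a rigid transform into rotation about an axis + axial slide.

    Raises
    ------
    GeometryError
        If the rotation part is within ``MIN_AXIS_ANGLE_DEG`` of the
        identity, where the axis is undefined.
    """
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle_rad = float(np.linalg.norm(rotvec))
    angle_deg = np.degrees(angle_rad)
    if angle_deg < MIN_AXIS_ANGLE_DEG:
        raise GeometryError("axis undefined: transform is (near-)identity rotation")
    axis = rotvec / angle_rad
    h = float(np.dot(t.translation, axis))
    axis, angle_deg, h = _orient_axis(axis, angle_deg, h)
    # Point on axis: solve (I - R) c = t_perp in the plane normal to the axis.
    t_perp = t.translation - np.dot(t.translation, axis) * axis
    A = np.eye(3) - t.rotation
    c, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    c = c - np.dot(c, axis) * axis
    return ScrewParameters(axis, c, float(angle_deg), h)


def screw_compose(params: ScrewParameters) -> RigidTransform:
    """Rebuild the rigid transform from its screw parameters."""
    R = Rotation.from_rotvec(
        np.radians(params.rotation_angle) * params.axis_direction
    ).as_matrix()
    c = params.axis_point
    t = c - R @ c + params.axial_translation * params.axis_direction
    return RigidTransform(R, t)
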