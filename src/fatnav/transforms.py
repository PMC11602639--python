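"""Rigid-body transform algebra and motion-severity scores.

A :class:`RigidTransform` holds 6 parameters: rotations about Z, Y and X in
degrees and translations in mm.  The forward action on a point ``p`` (in mm,
relative to the rotation centre) is *translate then rotate*,

    T(p) = R (p + t),     R = Rx(rx) · Ry(ry) · Rz(rz),

i.e. rotations are applied about Z first, then Y, then X, all extrinsic and
counterclockwise-positive looking down each axis — mirroring how a navigator
image is shifted and then rotated axis by axis.  Matrices act on column
vectors from the left; composition ``compose(a, b)`` means "apply b, then a".

The motion score summarises a transform's severity as the worst-case
displacement of any point on a 64 mm-radius sphere (a proxy for the head):
the rotational part contributes 2·r·sin(θ/2) for total rotation angle θ, and
the translational part its Euclidean norm.  The residual motion score of a
detected transform against a known ground truth is the motion score of
``detected ∘ ground_truth⁻¹`` and is the package's registration-error metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "MotionScoreReport",
    "compose",
    "invert",
    "rotation_displacement",
    "motion_score",
    "residual_motion_score",
    "HEAD_SPHERE_RADIUS_MM",
]

#: Radius of the sphere used for the worst-case rotational displacement;
#: a standard proxy for an adult head.
HEAD_SPHERE_RADIUS_MM = 64.0


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid-body transform (see module docstring for conventions).

    Attributes
    ----------
    rot_deg : tuple
        Rotations (rz, ry, rx) in degrees, applied in Z, Y, X order.
    trans_mm : tuple
        Translations (tx, ty, tz) in mm, applied before the rotations.
    center : str
        Rotation-centre convention tag; transforms can only be combined
        when their tags agree.
    """

    rot_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    trans_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: str = "volume_center"

    def __post_init__(self):
        object.__setattr__(self, "rot_deg", tuple(float(a) for a in self.rot_deg))
        object.__setattr__(self, "trans_mm", tuple(float(a) for a in self.trans_mm))
        if len(self.rot_deg) != 3 or len(self.trans_mm) != 3:
            raise ValueError("rot_deg and trans_mm must each have 3 entries")
        if not all(np.isfinite(self.rot_deg + self.trans_mm)):
            raise ValueError("transform parameters must be finite")

    # ----------------------------------------------------------- conversions
    @property
    def rotation(self) -> Rotation:
        # extrinsic z, then y, then x
        return Rotation.from_euler("zyx", self.rot_deg, degrees=True)

    @property
    def matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix for p ↦ R(p + t)."""
        R = self.rotation.as_matrix()
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = R @ np.asarray(self.trans_mm)
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray, center: str = "volume_center") -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("matrix is not a proper rotation")
        rot = Rotation.from_matrix(R)
        rz, ry, rx = rot.as_euler("zyx", degrees=True)
        t = R.T @ m[:3, 3]
        return cls((rz, ry, rx), tuple(t), center)

    @classmethod
    def identity(cls, center: str = "volume_center") -> "RigidTransform":
        return cls(center=center)

    # ----------------------------------------------------------------- algebra
    def apply_points(self, pts_mm: np.ndarray) -> np.ndarray:
        """Apply the forward map to an (n, 3) array of mm coordinates."""
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        return (self.rotation.as_matrix() @ (pts + np.asarray(self.trans_mm)).T).T

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.matrix, np.eye(4), atol=atol)
        )

    # --------------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "rot_deg": list(self.rot_deg),
            "trans_mm": list(self.trans_mm),
            "order": "ZYX",
            "center": self.center,
            "convention": "translate_then_rotate",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        if d.get("order", "ZYX") != "ZYX" or d.get("convention", "translate_then_rotate") != "translate_then_rotate":
            raise ValueError(f"unsupported transform convention in {d!r}")
        return cls(tuple(d["rot_deg"]), tuple(d["trans_mm"]), d.get("center", "volume_center"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class MotionScoreReport:
    """Decomposition of a motion score into its rotational and translational parts."""

    delta_R: float
    translation_norm: float

    @property
    def score(self) -> float:
        return self.delta_R + self.translation_norm


def _check_centers(a: RigidTransform, b: RigidTransform) -> None:
    if a.center != b.center:
        raise ValueError(
            f"cannot combine transforms with different centre conventions: "
            f"{a.center!r} vs {b.center!r}"
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``b`` first, then ``a`` (matrix product a·b)."""
    _check_centers(a, b)
    return RigidTransform.from_matrix(a.matrix @ b.matrix, a.center)


def invert(t: RigidTransform) -> RigidTransform:
    """Exact rigid inverse: rotation Rᵀ, translation −R·t."""
    m = np.eye(4)
    R = t.rotation.as_matrix()
    m[:3, :3] = R.T
    m[:3, 3] = -(R.T @ t.matrix[:3, 3])
    return RigidTransform.from_matrix(m, t.center)


def rotation_displacement(t: RigidTransform, radius_mm: float = HEAD_SPHERE_RADIUS_MM) -> float:
    """Worst-case displacement of a point on a sphere under the rotation of ``t``.

    For a rotation of total angle θ, the maximum of |R·p − p| over |p| = r is
    attained on the rotation-axis equator and equals 2·r·sin(θ/2).
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    theta = t.rotation.magnitude()  # radians, in [0, pi]
    return 2.0 * radius_mm * float(np.sin(theta / 2.0))


def motion_score(t: RigidTransform, radius_mm: float = HEAD_SPHERE_RADIUS_MM) -> MotionScoreReport:
    """Motion score ΔR + √(Δx² + Δy² + Δz²), in mm."""
    return MotionScoreReport(
        delta_R=rotation_displacement(t, radius_mm),
        translation_norm=float(np.linalg.norm(t.trans_mm)),
    )


def residual_motion_score(
    detected: RigidTransform,
    ground_truth: RigidTransform,
    radius_mm: float = HEAD_SPHERE_RADIUS_MM,
) -> float:
    """Motion score of the residual transform detected ∘ ground_truth⁻¹ (mm).

    Zero iff the detected transform equals the ground truth.
    """
    residual = compose(detected, invert(ground_truth))
    return motion_score(residual, radius_mm).score
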