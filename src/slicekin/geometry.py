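"""Rigid-body pose algebra and joint-coordinate-system displacement extraction.

A :class:`RigidPose` carries the position of a solid body in world
millimetres; a :class:`JointAxes` is the anatomical joint axis frame (AJX)
in which relative displacements between a stationary and a moving body are
reported.  Displacements are decomposed with an intrinsic x-y-z Euler
sequence; single-axis motions are convention-independent, and the chosen
sequence is fixed purely for reproducibility.

Sign conventions: +z is the direction of increasing scale reading in the
translation trials, and positive rotation follows the right-hand rule about
+x.  All lengths are millimetres, all angles degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "PoseError",
    "RigidPose",
    "JointAxes",
    "DisplacementRecord",
    "compose_poses",
    "jcs_displacement",
    "displacement_to_pose",
]

_ORTHO_TOL = 1e-9
#: Euler angles (about the middle axis of the intrinsic x-y-z sequence)
#: beyond which the decomposition approaches gimbal lock and is flagged.
GIMBAL_WARN_DEG = 80.0


class PoseError(ValueError):
    """Raised for invalid rotations or degenerate axis frames."""


def _check_rotation(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise PoseError(f"rotation must be 3x3, got {r.shape}")
    if not np.isfinite(r).all():
        raise PoseError("rotation contains non-finite entries")
    if np.abs(r.T @ r - np.eye(3)).max() > _ORTHO_TOL:
        raise PoseError("rotation is not orthonormal within 1e-9")
    if abs(np.linalg.det(r) - 1.0) > _ORTHO_TOL:
        raise PoseError("rotation determinant is not +1 within 1e-9")
    return r


def _orthonormalize(r: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) via SVD."""
    u, _, vt = np.linalg.svd(r)
    out = u @ vt
    if np.linalg.det(out) < 0:
        u[:, -1] *= -1
        out = u @ vt
    return out


@dataclass(frozen=True)
class RigidPose:
    """Rotation (3x3 orthonormal) plus translation (mm) of a solid body."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.isfinite(t).all():
            raise PoseError("translation contains non-finite entries")
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(cls, seq: str, angles_deg, translation=(0.0, 0.0, 0.0)) -> "RigidPose":
        rot = Rotation.from_euler(seq, angles_deg, degrees=True).as_matrix()
        return cls(rot, np.asarray(translation, dtype=float))

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return ``self ∘ other`` (apply *other* first, then *self*)."""
        r = self.rotation @ other.rotation
        drift = np.abs(r.T @ r - np.eye(3)).max()
        if drift > 1e-12:
            r = _orthonormalize(r)
        return RigidPose(r, self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidPose":
        rt = self.rotation.T
        return RigidPose(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from body to world coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def almost_equal(self, other: "RigidPose", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() <= tol
            and np.abs(self.translation - other.translation).max() <= tol
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [float(x) for x in self.rotation.ravel()],
            "translation_mm": [float(x) for x in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidPose":
        return cls(
            np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            np.asarray(d["translation_mm"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RigidPose":
        return cls.from_dict(json.loads(s))


def compose_poses(a: RigidPose, b: RigidPose) -> RigidPose:
    """Compose two poses: the result applies ``b`` first, then ``a``."""
    return a.compose(b)


@dataclass(frozen=True)
class JointAxes:
    """Anatomical joint axis frame: origin plus right-handed unit axes (mm)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.isfinite(v).all():
                raise PoseError(f"{name} contains non-finite entries")
            object.__setattr__(self, name, v)
        basis = self.basis
        if np.abs(basis.T @ basis - np.eye(3)).max() > _ORTHO_TOL:
            raise PoseError("joint axes are not orthonormal within 1e-9")
        if np.linalg.det(basis) < 0:
            raise PoseError("joint axes are left-handed")

    @property
    def basis(self) -> np.ndarray:
        """Columns are the x, y, z axes."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    @classmethod
    def standard(cls, origin=(0.0, 0.0, 0.0)) -> "JointAxes":
        return cls(np.asarray(origin, dtype=float), np.array([1.0, 0, 0]),
                   np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    def transformed(self, g: RigidPose) -> "JointAxes":
        """The same physical frame after a rigid world transform ``g``."""
        b = g.rotation @ self.basis
        return JointAxes(g.apply(self.origin), b[:, 0], b[:, 1], b[:, 2])

    def to_dict(self) -> dict:
        return {
            "origin_mm": [float(v) for v in self.origin],
            "x_axis": [float(v) for v in self.x_axis],
            "y_axis": [float(v) for v in self.y_axis],
            "z_axis": [float(v) for v in self.z_axis],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointAxes":
        return cls(
            np.asarray(d["origin_mm"], float), np.asarray(d["x_axis"], float),
            np.asarray(d["y_axis"], float), np.asarray(d["z_axis"], float),
        )


@dataclass(frozen=True)
class DisplacementRecord:
    """Six-DOF displacement of the moving body relative to neutral.

    Translations are in mm along the joint axes, rotations in degrees from
    an intrinsic x-y-z Euler decomposition.  The planar scalars reported in
    single-plane trials (``translation_z``, ``translation_x``,
    ``rotation_about_x``) are projections of the full 6-DOF record.
    """

    frame_index: int
    translations: np.ndarray  # (3,) mm, JCS x/y/z
    rotations_deg: np.ndarray  # (3,) deg, intrinsic x-y-z
    gimbal_warning: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "translations",
                           np.asarray(self.translations, float).reshape(3))
        object.__setattr__(self, "rotations_deg",
                           np.asarray(self.rotations_deg, float).reshape(3))

    @property
    def translation_x(self) -> float:
        return float(self.translations[0])

    @property
    def translation_y(self) -> float:
        return float(self.translations[1])

    @property
    def translation_z(self) -> float:
        return float(self.translations[2])

    @property
    def rotation_about_x(self) -> float:
        return float(self.rotations_deg[0])

    @property
    def full_6dof(self) -> np.ndarray:
        return np.concatenate([self.translations, self.rotations_deg])

    def to_dict(self) -> dict:
        return {
            "frame_index": int(self.frame_index),
            "translation_mm": [float(v) for v in self.translations],
            "rotation_deg": [float(v) for v in self.rotations_deg],
            "gimbal_warning": bool(self.gimbal_warning),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisplacementRecord":
        return cls(d["frame_index"], np.asarray(d["translation_mm"], float),
                   np.asarray(d["rotation_deg"], float),
                   bool(d.get("gimbal_warning", False)))

    def csv_row(self) -> dict:
        tx, ty, tz = self.translations
        rx, ry, rz = self.rotations_deg
        return {
            "frame": int(self.frame_index),
            "tx_mm": tx, "ty_mm": ty, "tz_mm": tz,
            "rx_deg": rx, "ry_deg": ry, "rz_deg": rz,
            "gimbal_warning": int(self.gimbal_warning),
        }


def _relative_pose(pose_a: RigidPose, pose_b: RigidPose) -> RigidPose:
    """Pose of body B expressed in body A's frame (world-independent)."""
    return pose_a.inverse().compose(pose_b)


def _axes_in_body_a(axes: JointAxes, neutral_a: RigidPose) -> tuple[np.ndarray, np.ndarray]:
    """JCS basis and origin pulled back into body A's neutral frame."""
    inv = neutral_a.inverse()
    return inv.rotation @ axes.basis, inv.apply(axes.origin)


def jcs_displacement(
    neutral_a: RigidPose,
    neutral_b: RigidPose,
    current_a: RigidPose,
    current_b: RigidPose,
    axes: JointAxes,
    frame_index: int = 0,
) -> DisplacementRecord:
    """Displacement of body B relative to body A, in the joint axes.

    The relative pose B-in-A is differenced against its neutral value; the
    change in rotation is decomposed as intrinsic x-y-z Euler angles about
    the joint axes and the change in relative translation is projected onto
    them.  Invariant to a common rigid transform of all four poses and the
    axes.  Configurations with the middle Euler angle within
    ``90 - GIMBAL_WARN_DEG`` degrees of gimbal lock are flagged.
    """
    rel_n = _relative_pose(neutral_a, neutral_b)
    rel_c = _relative_pose(current_a, current_b)
    basis, _ = _axes_in_body_a(axes, neutral_a)

    delta = rel_c.compose(rel_n.inverse())
    rot_jcs = basis.T @ delta.rotation @ basis
    angles = Rotation.from_matrix(rot_jcs).as_euler("XYZ", degrees=True)
    t_delta = basis.T @ (rel_c.translation - rel_n.translation)
    gimbal = bool(abs(angles[1]) > GIMBAL_WARN_DEG or abs(angles[2]) > GIMBAL_WARN_DEG)
    return DisplacementRecord(frame_index, t_delta, angles, gimbal)


def displacement_to_pose(record: DisplacementRecord, neutral_a: RigidPose,
                         neutral_b: RigidPose, axes: JointAxes) -> RigidPose:
    """Reconstruct the relative pose B-in-A implied by a displacement record.

    Inverse of :func:`jcs_displacement`: composing the record back through
    the joint axes reproduces the current relative pose.
    """
    rel_n = _relative_pose(neutral_a, neutral_b)
    basis, _ = _axes_in_body_a(axes, neutral_a)
    rot_jcs = Rotation.from_euler("XYZ", record.rotations_deg, degrees=True).as_matrix()
    delta_r = basis @ rot_jcs @ basis.T
    rel_c_rot = _orthonormalize(delta_r @ rel_n.rotation)
    rel_c_t = rel_n.translation + basis @ record.translations
    return RigidPose(rel_c_rot, rel_c_t)
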