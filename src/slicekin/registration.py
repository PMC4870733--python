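"""Automated rotoscoping: model-to-slice rigid registration.

The manual step of the original workflow — nudging a 3-D model until its
silhouette matches the image — is operationalized as maximization of the
zero-normalized cross-correlation (NCC) between the observed slice and a
predicted silhouette template, using a derivative-free Nelder-Mead simplex
with jittered restarts.  The template is produced by the same thick-slab
partial-volume operator as the simulator, but evaluated through the
calibrated volume mapping rather than ground-truth geometry, so a perfect
calibration reproduces the simulator's noiseless image exactly.

Degrees of freedom are masked per trial type (translation-z only,
rotation-x only, z+x for biplanar, or full 6-DOF); out-of-plane DOF are
weakly observable in single-plane slices and stay off by default.  The
rotation search is clamped to +/-45 degrees about each axis because the
bored cube has a 4-fold symmetry that creates equivalent basins every 90
degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .calibration import VolumeMapping
from .geometry import DisplacementRecord, JointAxes, RigidPose, jcs_displacement
from .imaging import SliceSpec, apply_blur
from .phantom import PosedSolid, TrialSeries, nominal_neutral_poses

__all__ = [
    "SilhouetteTemplate", "RegistrationResult", "RegistrationFailure",
    "model_cross_section", "match_score", "rotoscope_frame",
    "rotoscope_series", "extract_displacement_series", "series_measurements",
    "DOF_MASKS",
]

DOF_MASKS = {
    "tz": ("tz",),
    "tx": ("tx",),
    "rx": ("rx",),
    "tz+tx": ("tz", "tx"),
    "full": ("tx", "ty", "tz", "rx", "ry", "rz"),
}

#: rotation search bound (degrees) — inside the cube's 90-degree symmetry basin
ROTATION_CLAMP_DEG = 45.0
#: a frame whose best restart scores below this is declared a failure
DEFAULT_SCORE_THRESHOLD = 0.5


class RegistrationFailure(RuntimeError):
    """All restarts of a frame scored below the failure threshold."""


@dataclass
class SilhouetteTemplate:
    """Predicted partial-volume silhouette on the target pixel grid."""

    image: np.ndarray  # values in [0, 1], pre-blur
    empty: bool = False


@dataclass
class FrameResult:
    pose_a: RigidPose
    pose_b: RigidPose
    score: float
    n_evaluations: int
    restart_used: int
    failed: bool = False


@dataclass
class RegistrationResult:
    """Per-frame registered poses plus convergence diagnostics."""

    frames: list[FrameResult]
    axes: JointAxes
    dof_mask: str
    failures: list[int] = field(default_factory=list)

    @property
    def poses_a(self):
        return [f.pose_a for f in self.frames]

    @property
    def poses_b(self):
        return [f.pose_b for f in self.frames]

    @property
    def scores(self):
        return np.array([f.score for f in self.frames])

    def to_frame_rows(self):
        rows = []
        for i, f in enumerate(self.frames):
            for body, pose in (("a", f.pose_a), ("b", f.pose_b)):
                r = {"frame": i, "body": body, "score": f.score,
                     "failed": int(f.failed)}
                r.update({f"r{j}{k}": pose.rotation[j, k]
                          for j in range(3) for k in range(3)})
                tx, ty, tz = pose.translation
                r.update({"tx_mm": tx, "ty_mm": ty, "tz_mm": tz})
                rows.append(r)
        return rows


# ---------------------------------------------------------------------------
# template rendering and scoring


def _warped_sample_points(spec: SliceSpec, mapping: VolumeMapping,
                          supersample=(1, 1, 4)) -> np.ndarray:
    """World sample lattice of a slice, corrected through the calibration."""
    pts = spec.sample_points(supersample)
    return mapping.warp(pts.reshape(-1, 3)).reshape(pts.shape)


def _render_bodies(posed, sample_points: np.ndarray) -> np.ndarray:
    vals = np.zeros(sample_points.shape[:-1])
    flat = sample_points.reshape(-1, 3)
    for ps in posed:
        np.maximum(vals, ps.occupancy_world(flat).reshape(vals.shape), out=vals)
    return vals.mean(axis=0)


def model_cross_section(
    solid,
    pose: RigidPose,
    spec: SliceSpec,
    mapping: VolumeMapping,
    supersample=(1, 1, 4),
    sample_points: np.ndarray | None = None,
) -> SilhouetteTemplate:
    """Predicted slab cross-section of one posed solid (pre-blur).

    Shares the partial-volume operator with the simulator; the pixel
    lattice is carried into world space through the calibrated mapping.
    An empty template (slab misses the solid) is flagged, not an error.
    """
    if sample_points is None:
        sample_points = _warped_sample_points(spec, mapping, supersample)
    img = _render_bodies([PosedSolid(solid, pose)], sample_points)
    return SilhouetteTemplate(img, empty=bool(img.max() <= 0.0))


def match_score(template, observed: np.ndarray) -> float:
    """Zero-normalized cross-correlation in [-1, 1]; higher is better.

    A constant template or image carries no silhouette information and
    scores 0 (with a warning).
    """
    t = template.image if isinstance(template, SilhouetteTemplate) else np.asarray(template, float)
    o = np.asarray(observed, float)
    if t.shape != o.shape:
        raise ValueError(f"pixel grids differ: {t.shape} vs {o.shape}")
    tc = t - t.mean()
    oc = o - o.mean()
    st = np.sqrt((tc ** 2).sum())
    so = np.sqrt((oc ** 2).sum())
    if st < 1e-12 or so < 1e-12:
        warnings.warn("constant template or image; match score undefined",
                      stacklevel=2)
        return 0.0
    return float((tc * oc).sum() / (st * so))


# ---------------------------------------------------------------------------
# frame optimization


def _pose_from_params(init: RigidPose, params, dof_names) -> RigidPose:
    dt = np.zeros(3)
    rot_deg = np.zeros(3)
    for val, name in zip(params, dof_names):
        if name[0] == "t":
            dt["xyz".index(name[1])] = val
        else:
            rot_deg["xyz".index(name[1])] = np.clip(
                val, -ROTATION_CLAMP_DEG, ROTATION_CLAMP_DEG)
    if np.any(rot_deg):
        r = Rotation.from_euler("xyz", rot_deg, degrees=True).as_matrix() @ init.rotation
    else:
        r = init.rotation
    # rotations pivot about the body origin (the cube centre)
    return RigidPose(r, init.translation + dt)


def _rotation_penalty(params, dof_names) -> float:
    pen = 0.0
    for val, name in zip(params, dof_names):
        if name[0] == "r":
            over = abs(val) - ROTATION_CLAMP_DEG
            if over > 0:
                pen += 0.1 * over ** 2
    return pen


def _score_pose(pose_b, solid_b, observed, specs, static_imgs, points):
    total = 0.0
    for obs, spec, static, pts in zip(observed, specs, static_imgs, points):
        img = _render_bodies([PosedSolid(solid_b, pose_b)], pts)
        combined = np.maximum(img, static) if static is not None else img
        total += match_score(apply_blur(combined, spec), obs)
    return total / len(observed)


def rotoscope_frame(
    observed,
    specs,
    solids,
    init_poses,
    dof_mask: str,
    mapping: VolumeMapping,
    restarts: int = 5,
    rng: np.random.Generator | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    bodies: str = "b",
    supersample=(1, 1, 4),
    sample_points=None,
    xatol: float = 0.005,
) -> FrameResult:
    """Register one frame by derivative-free NCC maximization.

    ``observed``/``specs`` hold one or (biplanar) two slice images;
    ``solids`` and ``init_poses`` are the (A, B) pair, with initialization
    expected within the capture range (about +/-10 mm / +/-20 deg — in
    series mode the previous frame provides this).  ``bodies`` selects
    whether only the moving body B or, sequentially, both bodies are
    optimized.  Restarts beyond the first are jittered by +/-2 mm and
    +/-5 deg; if the best restart scores below ``score_threshold`` the
    frame is a :class:`RegistrationFailure`.
    """
    if dof_mask not in DOF_MASKS:
        raise ValueError(f"unknown dof_mask {dof_mask!r}; one of {sorted(DOF_MASKS)}")
    dof_names = DOF_MASKS[dof_mask]
    if rng is None:
        rng = np.random.default_rng(0)
    observed = list(observed)
    specs = list(specs)
    if sample_points is None:
        sample_points = [_warped_sample_points(s, mapping, supersample) for s in specs]
    solid_a, solid_b = solids
    pose_a, pose_b = init_poses
    n_eval = 0

    def optimize_body(moving_solid, moving_init, static_posed):
        nonlocal n_eval
        static_imgs = [
            _render_bodies([static_posed], pts) if static_posed is not None else None
            for pts in sample_points]

        def objective(params):
            nonlocal n_eval
            n_eval += 1
            pose = _pose_from_params(moving_init, params, dof_names)
            s = _score_pose(pose, moving_solid, observed, specs, static_imgs,
                            sample_points)
            return -s + _rotation_penalty(params, dof_names)

        best = None
        for r in range(max(restarts, 1)):
            x0 = np.zeros(len(dof_names))
            if r > 0:
                for i, name in enumerate(dof_names):
                    x0[i] = rng.uniform(-2.0, 2.0) if name[0] == "t" else rng.uniform(-5.0, 5.0)
            # explicit initial simplex: 2 mm / 4 deg steps (the default
            # simplex at x0 = 0 is microscopic and stalls the search)
            simplex = [np.array(x0, float)]
            for i, name in enumerate(dof_names):
                vert = np.array(x0, float)
                vert[i] += 2.0 if name[0] == "t" else 4.0
                simplex.append(vert)
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"xatol": xatol, "fatol": 1e-6,
                                    "initial_simplex": np.array(simplex),
                                    "maxiter": 200 * len(dof_names)})
            if best is None or res.fun < best[0].fun:
                best = (res, r)
        res, restart = best
        return _pose_from_params(moving_init, res.x, dof_names), -res.fun + _rotation_penalty(res.x, dof_names), restart

    restart_used = 0
    if bodies == "both":
        pose_a, _, _ = optimize_body(solid_a, pose_a, PosedSolid(solid_b, pose_b))
        pose_b, score, restart_used = optimize_body(solid_b, pose_b,
                                                    PosedSolid(solid_a, pose_a))
    elif bodies == "b":
        pose_b, score, restart_used = optimize_body(solid_b, pose_b,
                                                    PosedSolid(solid_a, pose_a))
    else:
        raise ValueError("bodies must be 'b' or 'both'")
    failed = score < score_threshold
    return FrameResult(pose_a, pose_b, float(score), n_eval, restart_used, failed)


# ---------------------------------------------------------------------------
# series processing


def rotoscope_series(
    series: TrialSeries,
    solids,
    mapping: VolumeMapping,
    dof_mask: str | None = None,
    init_poses=None,
    axes: JointAxes | None = None,
    restarts: int = 5,
    seed: int = 0,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    supersample=(1, 1, 4),
    poses_override=None,
) -> RegistrationResult:
    """Register every frame of a trial series in order.

    The neutral frame is registered for both bodies starting from
    ``init_poses`` (default: the nominal experimental placement); each
    later frame registers the moving body only, initialized at the
    previous frame's solution.  The joint axis frame is assigned at the
    neutral registration unless a saved ``axes`` is supplied (a second
    session reuses the first session's axes).  Failed frames are recorded
    and the series continues, the next frame initialized from the last
    success.  ``poses_override`` bypasses optimization with externally
    produced (pose_a, pose_b) pairs, keeping the manual workflow
    representable.
    """
    if dof_mask is None:
        dof_mask = {"translation_z": "tz", "rotation_x": "rx",
                    "biplanar": "tz+tx"}[series.trial_type]
    if init_poses is None:
        init_poses = nominal_neutral_poses()
    rng = np.random.default_rng(seed)

    if poses_override is not None:
        frames = [FrameResult(pa, pb, 1.0, 0, 0) for pa, pb in poses_override]
        if axes is None:
            axes = _assign_axes(frames[0])
        return RegistrationResult(frames, axes, dof_mask)

    spec_points = {}
    results: list[FrameResult] = []
    failures: list[int] = []
    pose_a, pose_b = init_poses
    for frame in series.frames:
        pts = []
        for spec in frame.specs:
            key = id(spec)
            if key not in spec_points:
                spec_points[key] = _warped_sample_points(spec, mapping, supersample)
            pts.append(spec_points[key])
        first = frame.index == 0
        fr = rotoscope_frame(
            frame.images, frame.specs, solids, (pose_a, pose_b), dof_mask,
            mapping, restarts=restarts, rng=rng,
            score_threshold=score_threshold, bodies="both" if first else "b",
            supersample=supersample, sample_points=pts)
        if first and fr.failed:
            raise RegistrationFailure(
                f"neutral frame failed to register (score {fr.score:.3f})")
        results.append(fr)
        if fr.failed:
            failures.append(frame.index)
        else:
            pose_a, pose_b = fr.pose_a, fr.pose_b
    if axes is None:
        axes = _assign_axes(results[0])
    return RegistrationResult(results, axes, dof_mask, failures)


def _assign_axes(neutral: FrameResult) -> JointAxes:
    """AJX aligned with the calibrated world frame, midway between the bodies."""
    origin = 0.5 * (neutral.pose_a.translation + neutral.pose_b.translation)
    return JointAxes.standard(origin)


def extract_displacement_series(result: RegistrationResult,
                                axes: JointAxes | None = None) -> list[DisplacementRecord]:
    """Per-frame joint-axis displacements relative to the neutral frame."""
    if axes is None:
        axes = result.axes
    neutral = result.frames[0]
    records = []
    for i, fr in enumerate(result.frames):
        records.append(jcs_displacement(neutral.pose_a, neutral.pose_b,
                                        fr.pose_a, fr.pose_b, axes,
                                        frame_index=i))
    return records


def series_measurements(records, trial_type: str) -> np.ndarray:
    """The trial-type-appropriate scalar(s) per frame.

    translation_z -> z translation (mm); rotation_x -> rotation about x
    (deg); biplanar -> (z, x) translations, shape (n, 2).
    """
    if trial_type == "translation_z":
        return np.array([r.translation_z for r in records])
    if trial_type == "rotation_x":
        return np.array([r.rotation_about_x for r in records])
    if trial_type == "biplanar":
        return np.array([[r.translation_z, r.translation_x] for r in records])
    raise ValueError(f"unknown trial_type {trial_type!r}")
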