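"""Synthetic phantom: solid-body cubes, the bead calibration grid, trial
series of MR-like slice images with retained ground truth, and a simulated
rater for exercising the reliability statistics.

The phantom reproduces the physical test objects of the technique: two
~40 mm cubes with hourglass-shaped bores (a stepped-cone drill feature that
gives the silhouette a distinctive bow-tie cross-section), and a
calibration grid of four plates, each carrying a 4x4 array of 2 mm beads at
20 mm pitch, stacked 30 mm apart along the scanner bore (y) axis.  Three
extra off-lattice beads on two adjacent plates break the lattice's 4-fold
symmetry and define the grid's x, y, z axes.

The signal model is deliberately minimal: material occupancy 1, air 0,
partial-volume averaging over the slab, Gaussian blur, additive Gaussian
noise.  No pulse-sequence contrast physics is modelled — the displacement
technique uses silhouette morphology only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import RigidPose
from .imaging import FAST_LIKE, T1_LIKE, SliceSpec, render_slice

__all__ = [
    "CubeSolid", "SphereSolid", "PosedSolid", "GridSpec", "TrialFrame",
    "TrialSeries", "SessionPairSim", "build_cube_solid",
    "grid_bead_coordinates", "generate_grid_scan", "generate_trial_series",
    "simulate_session_pair", "default_scene_solids", "nominal_neutral_poses",
]

#: z-offset of the moving cube's centre from the stationary cube's centre in
#: the neutral position: two 40 mm cubes with a ~10 mm gap between adjacent
#: faces, which is also the centre-of-rotation offset of the rotation trials.
NEUTRAL_SEPARATION_MM = 50.0


# ---------------------------------------------------------------------------
# solids


@dataclass(frozen=True)
class CubeSolid:
    """Cube with an hourglass (symmetric double-frustum) bore.

    The bore runs through the cube centre along ``bore_axis``; its radius
    tapers linearly from ``bore_base_diameter/2`` at the faces to
    ``bore_waist_diameter/2`` at the centre.  The waist diameter is not a
    measured quantity of the physical cubes and defaults to 3 mm.
    """

    side: float = 40.0
    bore_base_diameter: float = 7.0
    bore_waist_diameter: float = 3.0
    bore_axis: str = "y"

    def __post_init__(self) -> None:
        if not (0 < self.bore_waist_diameter <= self.bore_base_diameter < self.side):
            raise ValueError(
                "need 0 < waist <= base < side "
                f"(waist={self.bore_waist_diameter}, base={self.bore_base_diameter}, "
                f"side={self.side})")
        if self.bore_axis not in ("x", "y", "z"):
            raise ValueError(f"bore_axis must be x, y or z, got {self.bore_axis!r}")

    def occupancy(self, points: np.ndarray) -> np.ndarray:
        """Material occupancy (0/1) at body-frame points (..., 3)."""
        pts = np.asarray(points, dtype=float)
        half = self.side / 2.0
        inside = np.all(np.abs(pts) <= half, axis=-1)
        ax = "xyz".index(self.bore_axis)
        other = [i for i in range(3) if i != ax]
        along = np.abs(pts[..., ax])
        r_waist = self.bore_waist_diameter / 2.0
        r_base = self.bore_base_diameter / 2.0
        radius = r_waist + (r_base - r_waist) * np.minimum(along / half, 1.0)
        r2 = pts[..., other[0]] ** 2 + pts[..., other[1]] ** 2
        in_bore = r2 <= radius ** 2
        return (inside & ~in_bore).astype(float)

    def volume(self) -> float:
        """Analytic solid volume: cube minus two conical frusta (mm^3)."""
        h = self.side / 2.0
        r1 = self.bore_base_diameter / 2.0
        r2 = self.bore_waist_diameter / 2.0
        frustum = np.pi * h / 3.0 * (r1 ** 2 + r1 * r2 + r2 ** 2)
        return self.side ** 3 - 2.0 * frustum

    def voxelize(self, voxel: float = 0.5, supersample: int = 2):
        """Anti-aliased voxel mask; returns (fractions, voxel_size).

        Each voxel's value is the fraction of ``supersample**3``
        stratified sub-samples inside the solid, so the summed volume
        converges quickly to the analytic value.
        """
        half = self.side / 2.0
        n = int(np.ceil(self.side / voxel))
        centers = (np.arange(n) + 0.5) * voxel - half
        sub = ((np.arange(supersample) + 0.5) / supersample - 0.5) * voxel
        frac = np.zeros((n, n, n))
        for a in sub:
            for b in sub:
                for c in sub:
                    gx, gy, gz = np.meshgrid(centers + a, centers + b,
                                             centers + c, indexing="ij")
                    pts = np.stack([gx, gy, gz], axis=-1)
                    frac += self.occupancy(pts)
        return frac / supersample ** 3, voxel

    def voxel_volume(self, voxel: float = 0.5, supersample: int = 2) -> float:
        frac, vox = self.voxelize(voxel, supersample)
        return float(frac.sum() * vox ** 3)

    def to_mesh(self, voxel: float = 0.4):
        """Watertight triangle mesh (trimesh) via marching cubes."""
        import trimesh
        from skimage import measure

        frac, vox = self.voxelize(voxel, supersample=2)
        padded = np.pad(frac, 1)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
        verts = (verts - 1 + 0.5) * vox - self.side / 2.0
        # vertex merging (process=True) can break manifoldness here
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        if mesh.volume < 0:
            mesh.invert()
        return mesh


def build_cube_solid(**params) -> CubeSolid:
    """Construct and validate a cube solid (see :class:`CubeSolid`).

    ``bore_base_diameter=0`` yields a plain cube with no bore.
    """
    if params.get("bore_base_diameter", 7.0) == 0:
        side = params.get("side", 40.0)
        return _PlainCube(side=side)
    return CubeSolid(**params)


@dataclass(frozen=True)
class _PlainCube(CubeSolid):
    """Cube without a bore (bore parameters ignored)."""

    def __post_init__(self) -> None:  # skip bore validation
        pass

    def occupancy(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return np.all(np.abs(pts) <= self.side / 2.0, axis=-1).astype(float)

    def volume(self) -> float:
        return self.side ** 3


@dataclass(frozen=True)
class SphereSolid:
    """A water bead."""

    diameter: float = 2.0

    def occupancy(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (np.sum(pts ** 2, axis=-1) <= (self.diameter / 2.0) ** 2).astype(float)


@dataclass(frozen=True)
class PosedSolid:
    """A solid placed in the world by a rigid pose."""

    solid: object
    pose: RigidPose

    def occupancy_world(self, points: np.ndarray) -> np.ndarray:
        return self.solid.occupancy(self.pose.inverse().apply(points))


def default_scene_solids(cube_params: dict | None = None):
    """The stationary (A) and moving (B) cube solids of the displacement trials."""
    cube = build_cube_solid(**(cube_params or {}))
    return cube, cube


def nominal_neutral_poses() -> tuple[RigidPose, RigidPose]:
    """Design neutral placement: cube A at the origin, cube B 50 mm along +z."""
    return (RigidPose.identity(),
            RigidPose(np.eye(3), np.array([0.0, 0.0, NEUTRAL_SEPARATION_MM])))


# ---------------------------------------------------------------------------
# calibration grid


@dataclass(frozen=True)
class GridSpec:
    """Four-plate bead calibration grid.

    Plates are normal to the y (bore) axis at ``y = plate * plate_spacing``;
    each carries a ``beads_per_side`` x ``beads_per_side`` lattice of beads
    at ``bead_spacing`` pitch, centred on the plate.  ``axis_bead_offsets``
    are extra off-lattice beads, given as (plate, x, z), that define the
    grid axes and disambiguate lattice orientation.
    """

    n_plates: int = 4
    beads_per_side: int = 4
    bead_spacing: float = 20.0
    plate_spacing: float = 30.0
    bead_diameter: float = 2.0
    plate_side: float = 80.0
    # off-lattice and off-diagonal so every dihedral lattice symmetry is broken
    axis_bead_offsets: tuple = (
        (0, -38.0, -38.0), (0, -38.0, -10.0), (1, -38.0, -10.0))

    def __post_init__(self) -> None:
        extent = (self.beads_per_side - 1) * self.bead_spacing
        if extent > self.plate_side:
            raise ValueError("bead lattice does not fit on the plate")
        lattice = set()
        for x in self.lattice_offsets():
            for z in self.lattice_offsets():
                lattice.add((round(x, 6), round(z, 6)))
        for _, x, z in self.axis_bead_offsets:
            if (round(x, 6), round(z, 6)) in lattice:
                raise ValueError(f"axis bead at ({x}, {z}) coincides with a grid bead")
            if abs(x) > self.plate_side / 2 or abs(z) > self.plate_side / 2:
                raise ValueError(f"axis bead at ({x}, {z}) falls off the plate")

    def lattice_offsets(self) -> np.ndarray:
        n = self.beads_per_side
        return (np.arange(n) - (n - 1) / 2.0) * self.bead_spacing

    @property
    def beads_per_plate(self) -> int:
        return self.beads_per_side ** 2

    def plate_y(self, plate: int) -> float:
        return plate * self.plate_spacing


def grid_bead_coordinates(spec: GridSpec) -> dict[str, np.ndarray]:
    """Labelled world coordinates of every bead centre (the framespec).

    Lattice beads are labelled ``P{plate}R{row}C{col}`` with row indexing z
    and col indexing x; axis beads ``AX{i}``.  Plate *p* lies at
    ``y = p * plate_spacing``.
    """
    offsets = spec.lattice_offsets()
    out: dict[str, np.ndarray] = {}
    for p in range(spec.n_plates):
        y = spec.plate_y(p)
        for r, z in enumerate(offsets):
            for c, x in enumerate(offsets):
                out[f"P{p}R{r}C{c}"] = np.array([x, y, z])
    for i, (p, x, z) in enumerate(spec.axis_bead_offsets):
        out[f"AX{i}"] = np.array([x, spec.plate_y(p), z])
    return out


def plate_bead_labels(spec: GridSpec, plate: int) -> list[str]:
    """Labels of all beads (lattice + axis) lying on one plate."""
    labels = [f"P{plate}R{r}C{c}"
              for r in range(spec.beads_per_side)
              for c in range(spec.beads_per_side)]
    labels += [f"AX{i}" for i, (p, _, _) in enumerate(spec.axis_bead_offsets)
               if p == plate]
    return labels


def grid_slice_spec(spec: GridSpec, plate: int, pixel_size: float = 0.78125,
                    thickness: float = 3.0, shape=(256, 256),
                    noise_sigma: float = 0.0, blur_fwhm: float = 1.0) -> SliceSpec:
    """Acquisition geometry of the axial slice imaging one grid plate."""
    return SliceSpec(
        pixel_size=pixel_size, thickness=thickness, shape=shape,
        origin=np.array([0.0, spec.plate_y(plate), 0.0]),
        normal=np.array([0.0, 1.0, 0.0]), u_axis=np.array([1.0, 0.0, 0.0]),
        noise_sigma=noise_sigma, blur_fwhm=blur_fwhm)


def generate_grid_scan(spec: GridSpec, seed: int = 0, pixel_size: float = 0.78125,
                       noise_sigma: float = 0.0, blur_fwhm: float = 1.0,
                       thickness: float = 3.0):
    """Simulate the four axial bead-plate slices.

    Returns a list of dicts per plate with the image, its
    :class:`SliceSpec`, and the ground-truth bead centroids in pixel
    coordinates (label -> (u, v)) for validation.
    """
    rng = np.random.default_rng(seed)
    coords = grid_bead_coordinates(spec)
    bead = SphereSolid(spec.bead_diameter)
    scans = []
    for p in range(spec.n_plates):
        sspec = grid_slice_spec(spec, p, pixel_size=pixel_size,
                                thickness=thickness, noise_sigma=noise_sigma,
                                blur_fwhm=blur_fwhm)
        labels = plate_bead_labels(spec, p)
        scene = [PosedSolid(bead, RigidPose(np.eye(3), coords[lab]))
                 for lab in labels]
        img = render_slice(scene, sspec, rng=rng, supersample=(2, 2, 4))
        truth_px = {lab: tuple(sspec.world_to_pixel(coords[lab])[:2])
                    for lab in labels}
        scans.append({"plate": p, "image": img, "spec": sspec,
                      "truth_px": truth_px})
    return scans


# ---------------------------------------------------------------------------
# displacement trials


@dataclass(frozen=True)
class TrialFrame:
    """One scanned position: slice image(s) plus hidden ground truth."""

    index: int
    nominal: float  # mm or deg
    images: tuple  # one image, or two for biplanar
    specs: tuple  # matching SliceSpec per image
    pose_a: RigidPose
    pose_b: RigidPose


@dataclass(frozen=True)
class TrialSeries:
    """A coded series of displacement trials, neutral frame first."""

    trial_type: str  # translation_z | rotation_x | biplanar
    frames: tuple
    seed: int
    jitter: float

    def __post_init__(self) -> None:
        if self.trial_type not in ("translation_z", "rotation_x", "biplanar"):
            raise ValueError(f"unknown trial_type {self.trial_type!r}")

    @property
    def nominal_displacements(self) -> np.ndarray:
        return np.array([f.nominal for f in self.frames])

    def ground_truth_displacements(self) -> np.ndarray:
        """True displacement per frame relative to frame 0.

        For translation_z: z-offset of cube B; rotation_x: rotation angle
        about x in degrees; biplanar: (z, x) offsets, shape (n, 2).
        """
        ref = self.frames[0]
        if self.trial_type == "rotation_x":
            out = []
            for f in self.frames:
                rel = f.pose_b.rotation @ ref.pose_b.rotation.T
                out.append(np.degrees(Rotation.from_matrix(rel).as_rotvec()[0]))
            return np.array(out)
        deltas = np.array([f.pose_b.translation - ref.pose_b.translation
                           for f in self.frames])
        if self.trial_type == "biplanar":
            return deltas[:, [2, 0]]
        return deltas[:, 2]


def _trial_slice_specs(trial_type: str, slice_spec: SliceSpec):
    """Place the trial slice plane(s) so both cubes stay in view."""
    center = np.array([0.0, 0.0, 35.0])
    sagittal = replace(slice_spec, origin=center,
                       normal=np.array([1.0, 0.0, 0.0]),
                       u_axis=np.array([0.0, 0.0, 1.0]))
    if trial_type != "biplanar":
        return (sagittal,)
    axial = replace(slice_spec, origin=center,
                    normal=np.array([0.0, 1.0, 0.0]),
                    u_axis=np.array([0.0, 0.0, 1.0]))
    return (sagittal, axial)


def generate_trial_series(
    trial_type: str,
    displacement_levels,
    n_per_level: int,
    slice_spec: SliceSpec | None = None,
    seed: int = 0,
    jitter: float = 0.2,
    cube_params: dict | None = None,
) -> TrialSeries:
    """Simulate one coded trial series with hidden ground-truth poses.

    Frames enumerate every (level, replicate) pair, neutral (level 0, first
    replicate, zero jitter) first.  Each other frame realises its nominal
    displacement plus a uniform placement jitter of up to ``jitter`` mm (or
    degrees), emulating manual caliper positioning of the cubes.  Levels
    are mm for translation trials and degrees for rotation trials;
    biplanar frames displace cube B by the level in both z and x and carry
    two orthogonal slices.
    """
    levels = list(displacement_levels)
    if not levels:
        raise ValueError("displacement_levels must be non-empty")
    if slice_spec is None:
        slice_spec = SliceSpec(**T1_LIKE, noise_sigma=0.03, blur_fwhm=1.0)
    rng = np.random.default_rng(seed)
    cube_a, cube_b = default_scene_solids(cube_params)
    pose_a, neutral_b = nominal_neutral_poses()
    specs = _trial_slice_specs(trial_type, slice_spec)
    spts = [s.sample_points((1, 1, 4)) for s in specs]

    frames = []
    index = 0
    design = [(float(lv), n_per_level) for lv in sorted(set(levels))]
    if design[0][0] != 0.0:
        # ensure a neutral reference frame even when level 0 is not a trial
        design = [(0.0, 1)] + design
    for level, n_reps in design:
        for rep in range(n_reps):
            neutral_frame = index == 0
            if trial_type == "translation_z":
                jit = 0.0 if neutral_frame else rng.uniform(-jitter, jitter)
                t = neutral_b.translation + np.array([0.0, 0.0, level + jit])
                pose_b = RigidPose(np.eye(3), t)
            elif trial_type == "rotation_x":
                jit = 0.0 if neutral_frame else rng.uniform(-jitter, jitter)
                rot = Rotation.from_euler("x", level + jit, degrees=True).as_matrix()
                pose_b = RigidPose(rot, neutral_b.translation)
            elif trial_type == "biplanar":
                jz = 0.0 if neutral_frame else rng.uniform(-jitter, jitter)
                jx = 0.0 if neutral_frame else rng.uniform(-jitter, jitter)
                t = neutral_b.translation + np.array([level + jx, 0.0, level + jz])
                pose_b = RigidPose(np.eye(3), t)
            else:
                raise ValueError(f"unknown trial_type {trial_type!r}")
            scene = [PosedSolid(cube_a, pose_a), PosedSolid(cube_b, pose_b)]
            images = tuple(
                render_slice(scene, s, rng=rng, sample_points=pts)
                for s, pts in zip(specs, spts))
            frames.append(TrialFrame(index, float(level), images, specs,
                                     pose_a, pose_b))
            index += 1
    return TrialSeries(trial_type, tuple(frames), seed, jitter)


# ---------------------------------------------------------------------------
# simulated rater


@dataclass(frozen=True)
class SessionPairSim:
    """Model of a rater quantifying the same trials in two sessions.

    Each measurement is ``true + bias + Normal(0, sigma^2)`` with noise
    independent across trials and sessions.  ``bias_mode`` controls whether
    the systematic bias enters both sessions ("both") or only the second
    ("session2"), the latter emulating a between-session learning effect.
    """

    true_values: tuple
    rater_bias: float = 0.0
    rater_sigma: float = 0.0
    n_trials_per_level: int = 1
    seed: int = 0
    bias_mode: str = "both"

    def __post_init__(self) -> None:
        if self.rater_sigma < 0:
            raise ValueError("rater_sigma must be >= 0")
        if self.bias_mode not in ("both", "session2"):
            raise ValueError("bias_mode must be 'both' or 'session2'")

    def expanded_truth(self) -> np.ndarray:
        return np.repeat(np.asarray(self.true_values, float),
                         self.n_trials_per_level)


def simulate_session_pair(sim: SessionPairSim) -> tuple[np.ndarray, np.ndarray]:
    """Two equally-shaped sessions of noisy measurements of the same trials."""
    rng = np.random.default_rng(sim.seed)
    truth = sim.expanded_truth()
    n = truth.size
    s1 = truth + rng.normal(0.0, sim.rater_sigma, n) if sim.rater_sigma > 0 else truth.copy()
    s2 = truth + rng.normal(0.0, sim.rater_sigma, n) if sim.rater_sigma > 0 else truth.copy()
    if sim.bias_mode == "both":
        s1 = s1 + sim.rater_bias
        s2 = s2 + sim.rater_bias
    else:
        s2 = s2 + sim.rater_bias
    return s1, s2


# ---------------------------------------------------------------------------
# disk round trip (images as 16-bit TIFF + JSON sidecars, truth kept apart)


def save_trial_series(series: TrialSeries, outdir, include_truth: bool = True) -> None:
    """Write a trial series: TIFFs + sidecars + manifest CSV (+ truth JSON).

    Ground truth goes to a separate ``ground_truth.json`` so the
    registration stage can be run blinded.
    """
    import pathlib

    import pandas as pd
    import tifffile

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {"trial_type": series.trial_type, "seed": series.seed,
             "jitter": series.jitter, "frames": []}
    for f in series.frames:
        names = []
        for k, (img, spec) in enumerate(zip(f.images, f.specs)):
            name = f"frame{f.index:03d}_view{k}"
            arr = np.clip(img, 0.0, 1.0)
            tifffile.imwrite(outdir / f"{name}.tif",
                             (arr * 65535.0 + 0.5).astype(np.uint16))
            spec.write_sidecar(outdir / f"{name}.json", extra={"seed": series.seed})
            names.append(name)
        rows.append({"frame": f.index, "views": ";".join(names)})
        truth["frames"].append({
            "frame": f.index, "nominal": f.nominal,
            "pose_a": f.pose_a.to_dict(), "pose_b": f.pose_b.to_dict()})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    if include_truth:
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, sort_keys=True, indent=1)
            fh.write("\n")


def load_trial_series(outdir, trial_type: str, blind: bool = True) -> TrialSeries:
    """Read a trial series written by :func:`save_trial_series`.

    With ``blind=True`` (default) the ground-truth file is ignored and the
    frames carry identity placeholder poses and zero nominals.
    """
    import pathlib

    import pandas as pd
    import tifffile

    outdir = pathlib.Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    truth = None
    if not blind and (outdir / "ground_truth.json").exists():
        with open(outdir / "ground_truth.json") as fh:
            truth = json.load(fh)
    frames = []
    ident = RigidPose.identity()
    for _, row in manifest.iterrows():
        images, specs = [], []
        for name in str(row["views"]).split(";"):
            arr = tifffile.imread(outdir / f"{name}.tif").astype(float) / 65535.0
            images.append(arr)
            specs.append(SliceSpec.read_sidecar(outdir / f"{name}.json"))
        idx = int(row["frame"])
        nominal, pa, pb = 0.0, ident, ident
        if truth is not None:
            t = truth["frames"][idx]
            nominal = float(t["nominal"])
            pa = RigidPose.from_dict(t["pose_a"])
            pb = RigidPose.from_dict(t["pose_b"])
        frames.append(TrialFrame(idx, nominal, tuple(images), tuple(specs), pa, pb))
    seed = 0
    jitter = 0.0
    if truth is not None:
        seed, jitter = truth["seed"], truth["jitter"]
    return TrialSeries(trial_type, tuple(frames), seed, jitter)
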