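"""Slice-volume calibration from bead-grid images.

The chain mirrors the grid-digitization workflow of the technique: detect
bead centroids in each plate's slice image, establish bead correspondence
against the known grid geometry (the "framespec"), fit a normalized planar
DLT (homography) per plate, and assemble a volume mapping that carries
pixel coordinates of any slice into the calibrated world frame.

Two deliberate departures from a classical photogrammetric 11-parameter
DLT: each plate's control points are coplanar, which makes the 3-D DLT
degenerate, so an 8-parameter plane homography per plate is fitted instead
(with Hartley-style coordinate normalization, keeping stored coefficient
magnitudes <= 1); and because MR slices are tomographic rather than
projective, the volume model is affine-orthographic — a 3-D affine
correction from the scanner's nominal slice geometry to the grid's world
frame, with the known 30 mm plate spacing supplying the out-of-plane
scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu

from .imaging import SliceSpec
from .phantom import GridSpec, grid_bead_coordinates, plate_bead_labels

__all__ = [
    "DetectionError", "CorrespondenceError", "CalibrationError",
    "BeadCentroidSet", "PlateMapping", "VolumeMapping",
    "detect_bead_centroids", "correspond_beads", "fit_plate_mapping",
    "assemble_volume_mapping", "calibrate_from_scans",
]


class DetectionError(ValueError):
    """Bead detection found the wrong number of candidates."""

    def __init__(self, msg, candidates=None):
        super().__init__(msg)
        self.candidates = candidates if candidates is not None else []


class CorrespondenceError(ValueError):
    """Bead labelling could not be resolved unambiguously."""


class CalibrationError(ValueError):
    """Degenerate or inconsistent calibration fit."""


@dataclass
class BeadCentroidSet:
    """Pixel centroids of the beads in one plate image.

    ``labels`` is ``None`` until correspondence has been established, after
    which ``labels[i]`` names the bead at ``centroids[i]``.
    """

    plate_index: int
    centroids: np.ndarray  # (n, 2) as (u, v)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# detection


def detect_bead_centroids(
    image: np.ndarray,
    expected_count: int,
    pixel_size: float,
    bead_diameter: float = 2.0,
    threshold: float | None = None,
    plate_index: int = 0,
    presmooth_sigma: float = 0.7,
) -> BeadCentroidSet:
    """Detect bead centroids by threshold + connected components.

    The image is lightly smoothed, thresholded (Otsu unless ``threshold``
    is given), and connected components are kept if their area lies within
    [25%, 400%] of the nominal bead disc.  Centroids are intensity-weighted
    (background-subtracted) and therefore subpixel.  A count other than
    ``expected_count`` raises :class:`DetectionError` listing candidates.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    smooth = ndimage.gaussian_filter(img, presmooth_sigma) if presmooth_sigma else img
    if smooth.max() <= smooth.min():
        raise DetectionError("blank image: no candidates", candidates=[])
    if threshold is None:
        # Iterated Otsu: beads occupy a tiny image fraction, so a single
        # pass can land inside the background noise; re-threshold the
        # suprathreshold pixels until clear of the background level.
        bg_med = float(np.median(smooth))
        bg_sigma = 1.4826 * float(np.median(np.abs(smooth - bg_med)))
        thr = float(threshold_otsu(smooth))
        for _ in range(3):
            if thr > bg_med + 4.0 * bg_sigma:
                break
            above = smooth[smooth > thr]
            if above.size < 16 or above.max() <= above.min():
                break
            thr = float(threshold_otsu(above))
    else:
        thr = threshold
    mask = smooth > thr
    labels_arr, n_comp = ndimage.label(mask)
    disc_area = np.pi * (bead_diameter / 2.0 / pixel_size) ** 2
    lo, hi = 0.25 * disc_area, 4.0 * disc_area
    weights = np.clip(smooth - thr, 0.0, None)
    candidates = []
    for comp in range(1, n_comp + 1):
        sel = labels_arr == comp
        area = int(sel.sum())
        if not (lo <= area <= hi):
            continue
        w = weights * sel
        total = w.sum()
        if total <= 0:
            continue
        vv, uu = np.nonzero(sel)
        cu = float((uu * w[vv, uu]).sum() / total)
        cv = float((vv * w[vv, uu]).sum() / total)
        candidates.append((cu, cv))
    if len(candidates) != expected_count:
        raise DetectionError(
            f"detected {len(candidates)} beads, expected {expected_count}",
            candidates=candidates)
    return BeadCentroidSet(plate_index, np.array(candidates))


# ---------------------------------------------------------------------------
# correspondence


def _plate_pattern(grid: GridSpec, plate: int):
    """(labels, (n,2) world (x,z)) of the beads expected on one plate."""
    coords = grid_bead_coordinates(grid)
    labels = plate_bead_labels(grid, plate)
    pts = np.array([[coords[lab][0], coords[lab][2]] for lab in labels])
    return labels, pts


def _lattice_angle(points_mm: np.ndarray, spacing: float) -> float:
    """Dominant lattice direction modulo 90 degrees, in radians."""
    d = points_mm[:, None, :] - points_mm[None, :, :]
    dist = np.linalg.norm(d, axis=-1)
    sel = (dist > 0.7 * spacing) & (dist < 1.3 * spacing)
    if not sel.any():
        return 0.0
    ang = np.arctan2(d[sel][:, 1], d[sel][:, 0])
    # circular mean of angle*4 folds the 90-degree lattice symmetry away
    return float(np.angle(np.exp(4j * ang).mean()) / 4.0)


def _candidate_cost(pattern: np.ndarray, obs: np.ndarray, theta: float,
                    flip: bool):
    pat = pattern.copy()
    if flip:
        pat = pat @ np.array([[1.0, 0.0], [0.0, -1.0]])
    c, s = np.cos(theta), np.sin(theta)
    pat = pat @ np.array([[c, s], [-s, c]])
    pat = pat - pat.mean(axis=0) + obs.mean(axis=0)
    dmat = np.linalg.norm(pat[:, None, :] - obs[None, :, :], axis=-1)
    rows, cols = linear_sum_assignment(dmat)
    return float(dmat[rows, cols].sum()), cols


def correspond_beads(
    detected: BeadCentroidSet,
    grid: GridSpec,
    spec: SliceSpec,
    orientation_hint: tuple[bool, float] | None = None,
) -> BeadCentroidSet:
    """Assign bead labels to detected centroids.

    Lattice orientation is resolved by trying the four 90-degree rotations
    (and a reflection, since the slice may view the plate from either
    side) of the expected pattern and keeping the assignment with the
    lowest total distance; the off-lattice axis beads make this minimum
    unique.  On plates without axis beads a 4-fold symmetric cloud is
    genuinely ambiguous and a :class:`CorrespondenceError` is raised unless
    ``orientation_hint`` (the ``(flip, theta)`` resolved on an axis-bead
    plate of the same rigid grid) is supplied.
    """
    labels, pattern = _plate_pattern(grid, detected.plate_index)
    if len(detected.centroids) != len(labels):
        raise CorrespondenceError(
            f"plate {detected.plate_index}: {len(detected.centroids)} centroids "
            f"for {len(labels)} expected beads")
    obs = detected.centroids * spec.pixel_size
    has_axis = any(lab.startswith("AX") for lab in labels)

    if orientation_hint is not None:
        flip, theta = orientation_hint
        cost, assign = _candidate_cost(pattern, obs, theta, flip)
        chosen = (flip, theta, cost, assign)
    else:
        theta0 = _lattice_angle(obs, grid.bead_spacing)
        results = []
        for flip in (False, True):
            for k in range(4):
                theta = theta0 + k * np.pi / 2.0
                cost, assign = _candidate_cost(pattern, obs, theta, flip)
                results.append((cost, flip, theta, assign))
        results.sort(key=lambda r: r[0])
        best, second = results[0], results[1]
        if not has_axis and (second[0] - best[0]) < 0.05 * grid.bead_spacing * len(labels):
            raise CorrespondenceError(
                f"plate {detected.plate_index}: lattice orientation ambiguous "
                "(no axis beads in view)")
        chosen = (best[1], best[2], best[0], best[3])

    flip, theta, cost, assign = chosen
    if cost / len(labels) > 0.25 * grid.bead_spacing:
        raise CorrespondenceError(
            f"plate {detected.plate_index}: best assignment residual too large "
            f"({cost / len(labels):.2f} mm per bead)")
    ordered_labels = [None] * len(labels)
    for i, j in enumerate(assign):
        ordered_labels[j] = labels[i]
    out = BeadCentroidSet(detected.plate_index, detected.centroids,
                          list(ordered_labels))
    out.orientation = (flip, theta)
    return out


# ---------------------------------------------------------------------------
# plate homography (planar DLT)


@dataclass
class PlateMapping:
    """Normalized plane-to-image projective map for one grid plate."""

    plate_index: int
    coefficients: np.ndarray  # 3x3 homography world (x, z) -> pixel (u, v)
    rms_residual: float  # pixels
    beads: BeadCentroidSet | None = None
    slice_spec: SliceSpec | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.coefficients, float).reshape(3, 3)
        scale = np.abs(h).max()
        if scale == 0 or not np.isfinite(np.linalg.cond(h)):
            raise CalibrationError("plate homography is singular")
        self.coefficients = h / scale  # all stored coefficients have |.| <= 1

    def project(self, world_xz: np.ndarray) -> np.ndarray:
        """Map plate-plane coordinates (x, z) in mm to pixel (u, v)."""
        pts = np.asarray(world_xz, float).reshape(-1, 2)
        hom = np.column_stack([pts, np.ones(len(pts))]) @ self.coefficients.T
        return hom[:, :2] / hom[:, 2:3]

    def pixel_size_estimate(self) -> float:
        """Pixel pitch (mm/px) from the map's Jacobian at the plate centre."""
        eps = 1.0
        o = self.project([[0.0, 0.0]])
        jx = (self.project([[eps, 0.0]]) - o) / eps
        jz = (self.project([[0.0, eps]]) - o) / eps
        jac = np.column_stack([jx.ravel(), jz.ravel()])  # px per mm
        s = np.linalg.svd(jac, compute_uv=False)
        return float(1.0 / np.sqrt(s[0] * s[1]))


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform taking points to centroid 0, mean radius sqrt(2)."""
    c = pts.mean(axis=0)
    scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
    t = np.eye(3)
    t[0, 0] = t[1, 1] = scale
    t[:2, 2] = -scale * c
    return t


def fit_plate_mapping(corresponded: BeadCentroidSet, grid: GridSpec) -> PlateMapping:
    """Least-squares normalized-DLT homography fit for one plate.

    Requires >= 4 non-collinear corresponded beads.  Residuals are reported
    as the RMS Euclidean reprojection error in pixels.
    """
    if corresponded.labels is None:
        raise CalibrationError("centroids are not corresponded")
    coords = grid_bead_coordinates(grid)
    world = np.array([[coords[lab][0], coords[lab][2]]
                      for lab in corresponded.labels])
    px = corresponded.centroids
    if len(world) < 4:
        raise CalibrationError(f"need >= 4 beads, got {len(world)}")
    centered = world - world.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[1] < 1e-9 * grid.bead_spacing:
        raise CalibrationError("control points are collinear")

    tw = _hartley_normalization(world)
    tp = _hartley_normalization(px)
    wh = np.column_stack([world, np.ones(len(world))]) @ tw.T
    ph = np.column_stack([px, np.ones(len(px))]) @ tp.T
    a = []
    for (x, z, _), (u, v, _) in zip(wh, ph):
        a.append([x, z, 1, 0, 0, 0, -u * x, -u * z, -u])
        a.append([0, 0, 0, x, z, 1, -v * x, -v * z, -v])
    _, _, vt = np.linalg.svd(np.asarray(a))
    h_norm = vt[-1].reshape(3, 3)
    h = np.linalg.inv(tp) @ h_norm @ tw
    mapping = PlateMapping(corresponded.plate_index, h, 0.0, corresponded)
    pred = mapping.project(world)
    mapping.rms_residual = float(np.sqrt(np.mean(np.sum((pred - px) ** 2, axis=1))))
    return mapping


# ---------------------------------------------------------------------------
# volume mapping


@dataclass
class VolumeMapping:
    """Calibrated bidirectional map between slice pixels and world mm.

    Wraps a 3-D affine correction ``world = A @ nominal + b`` applied on
    top of each slice's nominal sidecar geometry; in a perfect scanner the
    correction is the identity.  ``pixel_size_est`` is recovered from the
    per-plate homographies against the framespec and is independent of the
    sidecar's nominal pixel size.
    """

    affine: np.ndarray  # (3, 3)
    offset: np.ndarray  # (3,)
    global_rms_mm: float
    pixel_size_est: float
    plates: list[PlateMapping] | None = None

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, float).reshape(3, 3)
        self.offset = np.asarray(self.offset, float).reshape(3)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise CalibrationError("volume affine is singular")

    @classmethod
    def identity(cls, pixel_size: float = 0.78125) -> "VolumeMapping":
        return cls(np.eye(3), np.zeros(3), 0.0, pixel_size)

    def warp(self, points: np.ndarray) -> np.ndarray:
        """Nominal world points -> calibrated world points."""
        return np.asarray(points, float) @ self.affine.T + self.offset

    def unwarp(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        return (np.asarray(points, float) - self.offset) @ inv.T

    def world_from_pixel(self, u, v, spec: SliceSpec, w=0.0) -> np.ndarray:
        return self.warp(spec.pixel_to_world(u, v, w))

    def pixel_from_world(self, points: np.ndarray, spec: SliceSpec) -> np.ndarray:
        return spec.world_to_pixel(self.unwarp(points))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "affine": [float(x) for x in self.affine.ravel()],
            "offset_mm": [float(x) for x in self.offset],
            "global_rms_mm": float(self.global_rms_mm),
            "pixel_size_est_mm": float(self.pixel_size_est),
        }
        if self.plates:
            d["plates"] = [
                {"plate": p.plate_index,
                 "coefficients": [float(x) for x in p.coefficients.ravel()],
                 "rms_residual_px": float(p.rms_residual)}
                for p in self.plates]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeMapping":
        plates = None
        if "plates" in d:
            plates = [PlateMapping(p["plate"],
                                   np.asarray(p["coefficients"]).reshape(3, 3),
                                   p["rms_residual_px"])
                      for p in d["plates"]]
        return cls(np.asarray(d["affine"]).reshape(3, 3),
                   np.asarray(d["offset_mm"]), d["global_rms_mm"],
                   d["pixel_size_est_mm"], plates)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "VolumeMapping":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_csv(self, path) -> None:
        """One coefficient per row, in the spirit of the camera-file export."""
        import pandas as pd

        rows = [{"name": f"affine_{i}{j}", "value": self.affine[i, j]}
                for i in range(3) for j in range(3)]
        rows += [{"name": f"offset_{'xyz'[i]}", "value": self.offset[i]}
                 for i in range(3)]
        rows.append({"name": "global_rms_mm", "value": self.global_rms_mm})
        rows.append({"name": "pixel_size_est_mm", "value": self.pixel_size_est})
        if self.plates:
            for p in self.plates:
                for i in range(3):
                    for j in range(3):
                        rows.append({"name": f"plate{p.plate_index}_h{i}{j}",
                                     "value": p.coefficients[i, j]})
                rows.append({"name": f"plate{p.plate_index}_rms_px",
                             "value": p.rms_residual})
        pd.DataFrame(rows).to_csv(path, index=False)


def assemble_volume_mapping(plates: list[PlateMapping], grid: GridSpec) -> VolumeMapping:
    """Collate the per-plate fits into one affine-orthographic volume model.

    The bead pixel coordinates of every plate are pushed through their
    slice's nominal sidecar geometry (plate spacing supplying the
    out-of-plane coordinate) and a single 3-D affine to the framespec world
    coordinates is fitted by least squares.  A global RMS residual above
    1 mm marks the plate fits as mutually inconsistent.
    """
    if len(plates) < 2:
        raise CalibrationError("need >= 2 fitted plates")
    coords = grid_bead_coordinates(grid)
    nominal, true = [], []
    for p in plates:
        if p.beads is None or p.beads.labels is None or p.slice_spec is None:
            raise CalibrationError(
                f"plate {p.plate_index} lacks corresponded beads or a slice spec")
        for (u, v), lab in zip(p.beads.centroids, p.beads.labels):
            nominal.append(p.slice_spec.pixel_to_world(u, v))
            true.append(coords[lab])
    nominal = np.asarray(nominal)
    true = np.asarray(true)
    design = np.column_stack([nominal, np.ones(len(nominal))])
    sol, *_ = np.linalg.lstsq(design, true, rcond=None)
    affine = sol[:3].T
    offset = sol[3]
    pred = nominal @ affine.T + offset
    rms = float(np.sqrt(np.mean(np.sum((pred - true) ** 2, axis=1))))
    if rms > 1.0:
        raise CalibrationError(
            f"plate mappings are inconsistent (global residual {rms:.2f} mm)")
    px = float(np.mean([p.pixel_size_estimate() for p in plates]))
    return VolumeMapping(affine, offset, rms, px, list(plates))


def calibrate_from_scans(scans, grid: GridSpec) -> VolumeMapping:
    """End-to-end calibration from per-plate scan dicts.

    ``scans`` is a sequence of dicts with keys ``plate``, ``image`` and
    ``spec`` (as produced by :func:`slicekin.phantom.generate_grid_scan`).
    Plates carrying axis beads are corresponded first; their resolved
    orientation seeds the symmetric plates.
    """
    hint = None
    fitted = {}
    order = sorted(scans, key=lambda s: -len(
        [1 for lab in plate_bead_labels(grid, s["plate"]) if lab.startswith("AX")]))
    for scan in order:
        p = scan["plate"]
        expected = len(plate_bead_labels(grid, p))
        det = detect_bead_centroids(scan["image"], expected,
                                    scan["spec"].pixel_size,
                                    grid.bead_diameter, plate_index=p)
        try:
            cor = correspond_beads(det, grid, scan["spec"])
        except CorrespondenceError:
            if hint is None:
                raise
            cor = correspond_beads(det, grid, scan["spec"], orientation_hint=hint)
        if hint is None and getattr(cor, "orientation", None) is not None:
            hint = cor.orientation
        pm = fit_plate_mapping(cor, grid)
        pm.slice_spec = scan["spec"]
        fitted[p] = pm
    plates = [fitted[p] for p in sorted(fitted)]
    return assemble_volume_mapping(plates, grid)
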