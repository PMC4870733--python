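# slicekin

Marker-less quantification of rigid-body displacements from single-plane
and biplanar MR-like slice images.

Measuring how two bones (say, adjacent vertebrae) move relative to each
other usually needs ionizing biplanar x-ray (XROMM/RSA-style) or implanted
markers. `slicekin` implements the non-ionizing alternative: calibrate the
MR slice-imaging volume with a bead grid, register 3-D solid models to
their silhouettes in thick-slab slice images (rotoscoping), and extract
joint-coordinate-system displacements — plus the complete test–retest
reliability analysis used to qualify such a technique. It is aimed at
musculoskeletal imaging researchers prototyping slice-based kinematics
pipelines.

Since no public dataset exists for this setup, the package ships a phantom
simulator that reproduces the validation hardware — two 40 mm cubes with
hourglass bores imaged at set displacements, and a 4-plate × 16-bead
calibration grid — with ground truth retained, so every stage runs and is
tested offline.

## Method at a glance

* **Calibration.** Bead centroids detected per plate image are
  corresponded to the known grid ("framespec") and fitted with a
  normalized planar DLT (homography) per plate, `u ~ H·(x, z, 1)ᵀ`.
  Because MR slices are tomographic, the volume model is
  affine-orthographic: a 3-D affine `x_world = A·x_nominal + b` correcting
  the scanner's nominal slice geometry, with the 30 mm plate spacing
  supplying the out-of-plane scale.
* **Rotoscoping.** For pose `(R, t)` of a solid, a thick-slab
  partial-volume template is rendered through the calibrated mapping and
  scored against the observed slice by zero-normalized cross-correlation;
  a Nelder–Mead simplex with restarts maximizes the score over the
  trial's degrees of freedom (z translation, x rotation, z+x biplanar, or
  full 6-DOF).
* **Kinematics.** The relative pose of the moving body w.r.t. the
  stationary body, differenced against neutral, is expressed in an
  anatomical joint axis frame: translations by projection, rotations by
  intrinsic x-y-z Euler decomposition.
* **Reliability.** Between-session CV (pair SD / mean × 100), ICC(2,1)
  (Shrout–Fleiss, F-based 95 % CI), paired/independent t-tests,
  Bland–Altman bias ± 1.96·SD limits with heteroscedasticity classified
  by R² of |differences| vs means at 0.1, and ratio limits of agreement
  `[(SDdiffs/AVGmeans) × 1.96] × 100`.

## Worked example

```python
import numpy as np
from slicekin import (GridSpec, SliceSpec, generate_trial_series,
                      rotoscope_series, extract_displacement_series,
                      series_measurements, calibrate_from_scans)
from slicekin.imaging import T1_LIKE
from slicekin.phantom import generate_grid_scan, default_scene_solids

# 1. calibrate the imaging volume from simulated grid slices
grid = GridSpec()
scans = generate_grid_scan(grid, seed=1, noise_sigma=0.03, blur_fwhm=1.0)
mapping = calibrate_from_scans(scans, grid)
print(f"pixel size {mapping.pixel_size_est:.5f} mm, "
      f"residual {mapping.global_rms_mm:.4f} mm")

# 2. simulate a coded translation series and register it blind
spec = SliceSpec(**T1_LIKE, noise_sigma=0.03, blur_fwhm=1.0)
series = generate_trial_series("translation_z", [0, 5, 10, 15, 20], 1,
                               slice_spec=spec, seed=2)
result = rotoscope_series(series, default_scene_solids(), mapping, seed=3)
measured = series_measurements(extract_displacement_series(result),
                               "translation_z")
truth = series.ground_truth_displacements()
print("measured:", np.round(measured, 3))
print("truth:   ", np.round(truth, 3))
print(f"max |error| = {np.abs(measured - truth).max():.3f} mm")
```

prints

```
pixel size 0.78180 mm, residual 0.0614 mm
measured: [ 0.     4.973 10.184 15.199 20.176]
truth:    [ 0.     4.965 10.165 15.183 20.164]
max |error| = 0.018 mm
```

The calibration recovers the T1-like pixel pitch (true value 0.78125 mm)
to 0.07 % with a sub-0.1 mm residual, and blind registration recovers the
set displacements (nominal levels plus the ±0.2 mm placement jitter) to
a few hundredths of a voxel at 3 % imaging noise.

The same workflow is available from the shell:

```sh
slicekin simulate  --seed 1 --out run/data
slicekin calibrate --grid-dir run/data/grid --out run/cal
slicekin rotoscope --series-dir run/data/translation_z \
    --trial-type translation_z \
    --mapping run/cal/volume_mapping.json --seed 5 --out run/s1
slicekin all       --seed 1 --out run   # the whole chain, two sessions
slicekin analyze \
    --session1 run/translation_z/session1/session_values.csv \
    --session2 run/translation_z/session2/session_values.csv \
    --out run/report                    # or any CSVs with level,trial_id,value
```

Ground truth is stored apart from the trial images, so the rotoscope stage
runs blinded; `--poses-from-file` accepts externally produced poses and
`--axes-file` lets a second session reuse the first session's joint axes.

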