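# scan2fem

Subject-specific finite-element meshes for thoracic electrical impedance
tomography (EIT), built from smartphone depth-sensor scans of a patient
wearing a 32-electrode belt.

Difference EIT images regional lung ventilation from boundary voltage
measurements, but reconstructing on a generic chest model misplaces and
distorts the lungs.  `scan2fem` turns a colored surface triangulation of
the thorax (a PLY file from any handheld 3D scanner) into a
subject-specific tetrahedral FEM mesh with the electrodes located and
numbered — and then into tidal-breathing difference images — with no
hardware beyond the phone and the belt.

**Who it is for:** EIT researchers who record thoracic data with
pairwise current-injection belts and want patient-specific forward
models without CT, and developers of scan-based anatomical modeling
pipelines.

## The method

1. **Crop & fiducial detection.**  The belt carries a sticker opposite
   every electrode; six stickers have known colors
   (7 = cyan, 12 = orange, 17 = red, 22 = yellow, 27 = green,
   32 = pink), the rest are white.  Color clusters on the scan are
   detected, and the anchors fix the belt winding direction so the white
   stickers are numbered by angular interpolation; electrodes hidden by
   the belt buckle are inferred from the angular gaps.
2. **Leveling.**  A total-least-squares plane is fit to the electrode
   centers; the scan is rigidly rotated so that plane is horizontal and
   translated so the electrode centroid is the origin.
3. **Surface fit.**  The belt-band surface is reduced to a smooth
   star-shaped radius field — a Fourier series in azimuth whose
   coefficients vary with height through a constant-plus-Gaussian RBF
   basis:

   r(θ, z) = Σₘ Σₖ C[m,k] ψₘ(θ) φₖ(z),  ψ = {1, cos θ, sin θ, …, cos Nθ, sin Nθ}

   At the defaults N = 12, M = 7 the entire boundary is 175 numbers.
4. **Electrode-encoded remeshing.**  Persson–Strang force-equilibrium
   remeshing on the fitted surface, with a sizing field that refines to
   0.5 mm on the 5 mm-radius electrode discs and coarsens to 5 mm in the
   background; every disc rim is resolved by mesh edges.
5. **FEM mesh.**  The belt-band solid (tube plus flat caps) is
   tetrahedralized by a Delaunay-with-inside-filter generator with graded
   interior seeding; electrode facet labels transfer onto the boundary.
6. **EIT imaging.**  A P1 complete-electrode-model forward solver
   (contact impedance, skip-4 pairwise injection at 3 mA, ~48 Hz frames)
   with adjoint sensitivities feeds a one-step Gauss–Newton
   reconstruction with Tikhonov regularization on baseline-normalized
   voltages: δσ = (JₙᵀJₙ + λI)⁻¹ Jₙᵀ (v₁−v₀)/v₀.  Tidal images difference
   the mean end-inhale against the mean end-exhale frames found by
   prominence-based peak detection of the global voltage signal.

Validation metrics (orthogonal-Procrustes rigid alignment, electrode
RMS/max differences, contour-to-surface distances) quantify scan
precision (scan-to-scan) and accuracy (scan-to-tracked-ground-truth),
and a synthetic phantom generator produces colored scans, tracked
points, and simulated two-lung EIT sequences for testing everything
end to end.

## Worked example

Generate a synthetic thorax scan (100 cm belt perimeter, 2 mm
scanner-like noise) and run the full pipeline:

```bash
scan2fem simulate --seed 3 --perimeter 1000 --noise 2.0 --outdir phantom
scan2fem run --in phantom/scan.ply --config config.json --seed 3 --outdir out
```

with `config.json` containing
`{"crop": {"z_bounds": [-55, 55]}, "mesh": {"h_electrode": 2.0, "h_background": 10.0, "electrode_radius": 5.0}}`
(test-scale mesh densities; pass `--fine-h` to `scan2fem mesh` for the
production 0.5/5 mm values).  The report printed:

```json
{
  "stages": {
    "load/crop":   {"seconds": 0.30, "n_vertices": 109886},
    "electrodes":  {"seconds": 1.39, "n_labeled": 32, "occluded": []},
    "leveling":    {"seconds": 0.005},
    "surface-fit": {"seconds": 5.02, "n_parameters": 175,
                    "residual_rms_mm": 0.888},
    "mesh":        {"seconds": 8.42, "n_nodes": 12190, "n_elements": 72246,
                    "total_volume_mm3": 8998430.4, "z_extent_mm": 115.7}
  },
  "seed": 3
}
```

All 32 electrodes were detected and numbered; the 175-parameter boundary
model reproduces the noisy 110 k-vertex scan with 0.89 mm RMS residual;
the tetrahedral mesh spans the cropped belt band.  Comparing the
detected electrodes against the phantom's tracked ground truth:

```bash
scan2fem validate --scans phantom/tracked_electrodes.csv --scans out/electrodes.csv
```

```json
{"precision": {"n_comparisons": 1, "rms_mean_mm": 2.55, "max_mean_mm": 5.01}}
```

i.e. a 2.5 mm RMS electrode-position error at this noise level — the
few-millimeter regime of real handheld scans.

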