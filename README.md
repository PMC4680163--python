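# haemquant

Measurement methods for intracerebral haemorrhage (ICH) volume on CT,
evaluated against synthetic phantoms with analytically known ground truth.

Acute haematoma volume drives prognosis and trial eligibility in ICH, but it
is measured in practice with methods of very different cost and behaviour:
the bedside ellipsoid approximation ABC/2, its slice-weighted modification,
semiautomated threshold planimetry (SAS) and fully automatic region growing
(AVC). `haemquant` is for methodologists who want to study how these methods
disagree — as a function of lesion size, shape irregularity and density
heterogeneity — without needing patient imaging: it renders CT-like phantoms
whose true volume is computable, runs every method on them, and summarises
agreement the way method-comparison studies do (ICC, Bland–Altman,
paired differences).

## Methods implemented

* **ABC/2** — `V = A·B·C/2`, with `A` the longest axial in-plane diameter,
  `B` the longest extent at 90° to `A` on the same slice, `C` the summed
  thickness of slices showing haemorrhage. Exact for an ellipsoid up to the
  factor `(1/2)/(π/6) = 3/π`.
* **Modified ABC/2** — each slice contributes 0, 0.5 or 1 of its thickness
  to `C` according to whether its haemorrhage area is `<25 %`, `25–75 %` or
  `>75 %` of the largest slice's area.
* **SAS** — per-slice planimetric areas of an HU-thresholded,
  connected-component-restricted, manually editable ROI, summed × thickness.
* **AVC** — seeded 3D region growing in the HU window; refuses series with
  varying slice thickness, as the automatic tooling it mirrors does.
* **Morphometry** — largest-slice area, perimeter, mean and SD of
  attenuation; shape index `P/(2√(πA))` (1 for a disc); density index
  `SD/mean` (the coefficient of variation).
* **IVH scores** — classic Graeb (0–12) and an eight-compartment modified
  Graeb scale (0–32), driven by YAML schemas.
* **Agreement layer** — two-way ICCs from variance components (absolute
  ICC(2,1) and consistency ICC(3,1)), Bland–Altman limits of agreement with
  a difference-on-mean regression, paired t / Wilcoxon, Spearman rank
  correlation.

## Worked example

Run the full in-silico method-comparison study on the default cohort
(100 phantoms spanning <3 / 3–4.9 / 5–8 / >8 cm size categories, ~64 %
irregular, two simulated observers, two sessions):

```python
from haemquant import StudyConfig, run_study, write_report

report = run_study(StudyConfig(seed=7))
write_report(report, "report/")
print(report.bland_altman.round(3))
```

```
     method_x method_y  mean_diff  slope    r2  p_slope
modified_abc2     abc2     -9.319 -0.439 0.982      0.0
          sas     abc2     -1.699 -0.078 0.286      0.0
modified_abc2      sas     -7.621 -0.365 0.907      0.0
```

Reading this: modified ABC/2 underestimates both standard ABC/2 and SAS, and
the underestimation grows with haematoma size (negative difference-on-mean
slopes near −0.4), whereas ABC/2 and SAS track each other closely. The split
by shape class shows the same asymmetry — the mean ABC/2 − modified-ABC/2
difference is 4.2 cm³ for regular phantoms and 12.2 cm³ for irregular ones —
and the intra- and interobserver ICCs of all three methods exceed 0.98 under
the default observer-noise model.

Single operations work standalone:

```python
from haemquant import (PhantomSpec, generate_phantom, segment_threshold,
                       SegmentationParams, window_from_tissue, measure_all)

spec = PhantomSpec(ellipsoid_diameters=(40, 30, 20), centre=(30, 30, 20),
                   grid_rows=60, grid_cols=60, slice_thicknesses=(1.0,) * 40,
                   noise_sd_hu=0.0, hetero_sd_hu=0.0)
volume, truth = generate_phantom(spec)            # truth: 12.57 cm^3 oracle
params = SegmentationParams(*window_from_tissue(30, 65))
estimates = measure_all(volume, params)
print(estimates["abc2"].volume_cm3)               # 12.03  (= 3/pi * oracle)
print(estimates["sas"].volume_cm3)                # 12.60
```

A command-line interface wraps the same library:

```bash
haemquant generate --config cohort.yaml --seed 4 --out phantoms/
haemquant measure --volume phantoms/phantom_0000.nii.gz --out meas.csv
haemquant score-ivh --state state.csv --schema mgs32
haemquant run-study --config study.yaml --out report/
```

Volumes are NIfTI files with a `<name>.meta.json` sidecar carrying the
authoritative per-slice thickness vector and HU calibration (NIfTI headers
assume uniform spacing).

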