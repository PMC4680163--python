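"""Shared fixtures: noise-free reference phantoms and the default cohort.

Everything is generated programmatically at test time; the default cohort is
session-scoped because rendering 100 phantoms dominates suite runtime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from haemquant import (
    CohortConfig,
    CTVolume,
    PhantomSpec,
    SegmentationParams,
    generate_cohort,
    generate_phantom,
    measure_all,
    window_from_tissue,
)

#: HU window derived the way an operator samples lesion and brain tissue
MIDPOINT_PARAMS = SegmentationParams(*window_from_tissue(30.0, 65.0))


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noise-free 20 mm sphere at 1 mm isotropic; oracle 4.19 cm^3."""
    spec = PhantomSpec(
        ellipsoid_diameters=(20.0, 20.0, 20.0),
        centre=(20.0, 20.0, 20.0),
        grid_rows=40,
        grid_cols=40,
        slice_thicknesses=(1.0,) * 40,
        noise_sd_hu=0.0,
        hetero_sd_hu=0.0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Noise-free axis-aligned 40 x 30 x 20 mm ellipsoid at 1 mm isotropic."""
    spec = PhantomSpec(
        ellipsoid_diameters=(40.0, 30.0, 20.0),
        centre=(30.0, 30.0, 20.0),
        grid_rows=60,
        grid_cols=60,
        slice_thicknesses=(1.0,) * 40,
        noise_sd_hu=0.0,
        hetero_sd_hu=0.0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 100-phantom cohort at seed 0."""
    return generate_cohort(CohortConfig(), seed=0)


@pytest.fixture(scope="session")
def default_cohort_measurements(default_cohort):
    """Direct (noise-free observer) measurements of the default cohort."""
    scans, manifest = default_cohort
    rows = []
    for (vol, truth), sid in zip(scans, manifest["scan_id"]):
        est = measure_all(vol, MIDPOINT_PARAMS)
        rows.append(
            {
                "scan_id": sid,
                "true_volume_cm3": truth.true_volume_cm3,
                "shape_class": truth.shape_class,
                "longest_diameter_cm": truth.longest_diameter_cm,
                "abc2": est["abc2"].volume_cm3,
                "modified_abc2": est["modified_abc2"].volume_cm3,
                "sas": est["sas"].volume_cm3,
            }
        )
    return pd.DataFrame(rows)


def binary_volume(values: np.ndarray, spacing: float = 1.0) -> CTVolume:
    """Helper: wrap a hand-built HU array as a CTVolume with 1 mm slices."""
    return CTVolume(
        values=values.astype(np.float32),
        in_plane_spacing=spacing,
        slice_thicknesses=np.full(values.shape[0], 1.0),
    )
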