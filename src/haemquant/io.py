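"""Reading and writing volumes, manifests and ventricular states.

Volumes are stored as NIfTI with a JSON sidecar ``<volume>.meta.json``.
NIfTI headers assume uniform through-plane spacing, so the sidecar carries
the authoritative per-slice thickness vector and the HU calibration (slope
and intercept mapping stored values to Hounsfield units).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .ivh import VentricularState
from .phantom import CTVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_manifest",
    "load_manifest",
    "save_ventricular_state",
    "load_ventricular_state",
]


def _sidecar_path(nifti_path: Path) -> Path:
    name = nifti_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return nifti_path.with_name(name[: -len(suffix)] + ".meta.json")
    return nifti_path.with_suffix(".meta.json")


def save_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a CT volume as NIfTI plus its authoritative metadata sidecar.

    The NIfTI array axes are (x=column, y=row, z=slice) per convention; the
    header's z spacing is the mean thickness and is advisory only.
    """
    path = Path(path)
    # NIfTI convention: fastest axis first -> transpose (slice,row,col) to (col,row,slice)
    data = np.ascontiguousarray(volume.values.transpose(2, 1, 0)).astype(np.float32)
    affine = np.diag(
        [
            volume.in_plane_spacing,
            volume.in_plane_spacing,
            float(volume.slice_thicknesses.mean()),
            1.0,
        ]
    )
    nib.save(nib.Nifti1Image(data, affine), str(path))
    meta = {
        "in_plane_spacing_mm": volume.in_plane_spacing,
        "slice_thicknesses_mm": [float(t) for t in volume.slice_thicknesses],
        "hu_calibration": {"slope": 1.0, "intercept": 0.0},
        "axis_order": "values[slice, row, column]; slice 0 most inferior",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def load_volume(path: str | Path, meta_path: str | Path | None = None) -> CTVolume:
    """Load a NIfTI volume, taking spacing from the sidecar when present."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0)
    meta_file = Path(meta_path) if meta_path else _sidecar_path(path)
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        spacing = float(meta["in_plane_spacing_mm"])
        thick = np.asarray(meta["slice_thicknesses_mm"], dtype=float)
        cal = meta.get("hu_calibration", {"slope": 1.0, "intercept": 0.0})
        data = data * cal["slope"] + cal["intercept"]
    else:
        zooms = img.header.get_zooms()
        spacing = float(zooms[0])
        thick = np.full(data.shape[0], float(zooms[2]))
    return CTVolume(values=data, in_plane_spacing=spacing, slice_thicknesses=thick)


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, index=False)
    return path


def load_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_ventricular_state(state: VentricularState, path: str | Path) -> Path:
    """One row per compartment (CSV) or a JSON object, chosen by extension."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "fills": dict(state.fills),
            "trace": sorted(state.trace),
            "expanded": sorted(state.expanded),
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        rows = [
            {
                "compartment": name,
                "fill_fraction": fill,
                "trace": name in state.trace,
            }
            for name, fill in state.fills.items()
        ]
        df = pd.DataFrame(rows)
        df["expanded_ventricles"] = ";".join(sorted(state.expanded))
        df.to_csv(path, index=False)
    return path


def load_ventricular_state(path: str | Path) -> VentricularState:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return VentricularState(
            fills={k: float(v) for k, v in payload["fills"].items()},
            trace=frozenset(payload.get("trace", [])),
            expanded=frozenset(payload.get("expanded", [])),
        )
    df = pd.read_csv(path)
    expanded: frozenset[str] = frozenset()
    if "expanded_ventricles" in df.columns and len(df):
        raw = df["expanded_ventricles"].iloc[0]
        if isinstance(raw, str) and raw:
            expanded = frozenset(raw.split(";"))
    trace = frozenset(df.loc[df.get("trace", False) == True, "compartment"])
    return VentricularState(
        fills=dict(zip(df["compartment"], df["fill_fraction"].astype(float))),
        trace=trace,
        expanded=expanded,
    )
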