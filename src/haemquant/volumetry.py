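"""Haematoma volume measurement on CT volumes.

Four methods, all operating on a thresholded lesion mask or its diameters:

* ``abc2`` — the bedside ellipsoid approximation A x B x C / 2, where A is
  the longest axial in-plane diameter (cm), B the longest extent at 90
  degrees to A on the same slice, and C the craniocaudal extent covered by
  slices showing haemorrhage;
* ``modified_abc2`` — the same product but with each slice contributing 0,
  0.5 or 1 of its thickness to C according to whether its haemorrhage area is
  below 25 %, between 25 % and 75 %, or above 75 % of the largest slice area;
* ``sas`` — semiautomated segmentation: per-slice planimetric areas within an
  HU window, summed and multiplied by slice thickness;
* ``avc`` — automatic volume calculation: seeded 3D region growing within the
  HU window; mirrors tooling that requires uniform slice thickness and
  refuses series where it varies.

Internal lengths are in mm; reported diameters are cm and volumes cm^3, with
unit conversion confined to the reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.ndimage import binary_fill_holes
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label

from .phantom import CTVolume

__all__ = [
    "DiameterTriple",
    "SegmentationParams",
    "LesionMask",
    "VolumeEstimate",
    "NoLesionInWindowError",
    "SeedNotInWindowError",
    "VariableSliceThicknessError",
    "segment_threshold",
    "slice_areas",
    "measure_A_B",
    "c_standard",
    "c_modified",
    "abc2",
    "sas_volume",
    "avc_volume",
    "measure_all",
    "size_category",
    "slice_boundary_polygons",
    "window_from_tissue",
    "SIZE_CATEGORIES",
]

SIZE_CATEGORIES = ("<3", "3-4.9", "5-8", ">8")

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


class NoLesionInWindowError(ValueError):
    """Thresholding produced no voxels."""

    def __init__(self, hu_low: float, hu_high: float):
        self.window = (hu_low, hu_high)
        super().__init__(f"no lesion in window [{hu_low}, {hu_high}] HU")


class SeedNotInWindowError(ValueError):
    """The growing seed point falls outside the HU window."""


class VariableSliceThicknessError(ValueError):
    """Automatic volume calculation refuses variable-thickness series."""

    def __init__(self) -> None:
        super().__init__(
            "variable slice thickness unsupported by automatic volume "
            "calculation; pass allow_variable_thickness=True to override"
        )


@dataclass(frozen=True)
class DiameterTriple:
    """The A, B, C diameters (cm) feeding the ABC/2 family."""

    A_cm: float
    B_cm: float
    C_cm: float
    a_slice_index: int = 0

    def __post_init__(self) -> None:
        if not (self.A_cm >= self.B_cm > 0):
            raise ValueError(
                f"diameters must satisfy A >= B > 0 (got A={self.A_cm}, B={self.B_cm})"
            )
        if self.C_cm <= 0:
            raise ValueError(f"C must be positive (got {self.C_cm})")


@dataclass(frozen=True)
class SegmentationParams:
    """HU window and connectivity for threshold segmentation.

    ``fill_holes`` closes per-slice holes left by hypoattenuating lesion
    interior (the planimetric ROI outlines the lesion boundary, so interior
    holes count toward the area, as they do when a boundary is drawn or
    edited by hand).  ``include_mask``/``exclude_mask`` are voxel-level
    manual edits; include overrides exclude overrides the threshold.
    """

    hu_low: float = 40.0
    hu_high: float = 80.0
    connectivity: Literal[6, 18, 26] = 26
    seed_point: tuple[int, int, int] | None = None  # (slice, row, col)
    fill_holes: bool = True
    include_mask: np.ndarray | None = None
    exclude_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hu_low >= self.hu_high:
            raise ValueError("hu_low must be below hu_high")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class LesionMask:
    """Binary voxel mask congruent with its parent CT volume."""

    voxels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class VolumeEstimate:
    method: Literal["abc2", "modified_abc2", "sas", "avc"]
    volume_cm3: float
    triple: DiameterTriple | None = None

    def __post_init__(self) -> None:
        if self.volume_cm3 < 0:
            raise ValueError("volume must be >= 0")


def window_from_tissue(background_hu: float, lesion_hu: float,
                       upper_margin_hu: float = 15.0) -> tuple[float, float]:
    """Derive an HU window the way an operator samples lesion and brain.

    The lower bound is the midpoint between background and lesion attenuation
    (the decision boundary an operator converges on when sampling both
    tissues), the upper bound sits a margin above the lesion mean.  On
    partial-volume-rendered boundaries a midpoint threshold classifies a
    voxel as lesion exactly when lesion occupies the majority of it, which
    keeps planimetric volumes unbiased.
    """
    return (0.5 * (background_hu + lesion_hu), lesion_hu + upper_margin_hu)


def _component_mask(
    window: np.ndarray,
    connectivity: int,
    seed_point: tuple[int, int, int] | None,
) -> np.ndarray:
    labels = label(window, connectivity=_CONNECTIVITY_RANK[connectivity])
    if seed_point is not None:
        lab = labels[tuple(seed_point)]
        if lab == 0:
            raise SeedNotInWindowError(
                f"seed point {tuple(seed_point)} is not inside the HU window"
            )
        return labels == lab
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def segment_threshold(volume: CTVolume, params: SegmentationParams) -> LesionMask:
    """Threshold the HU window and keep one connected component.

    The component containing ``seed_point`` is kept when a seed is given,
    otherwise the largest.  Manual edits are applied last: include overrides
    exclude overrides the threshold result.
    """
    window = (volume.values >= params.hu_low) & (volume.values <= params.hu_high)
    if not window.any():
        raise NoLesionInWindowError(params.hu_low, params.hu_high)
    mask = _component_mask(window, params.connectivity, params.seed_point)
    if params.fill_holes:
        filled = np.empty_like(mask)
        for k in range(mask.shape[0]):
            filled[k] = binary_fill_holes(mask[k])
        mask = filled
    edits = {}
    if params.exclude_mask is not None:
        mask = mask & ~np.asarray(params.exclude_mask, dtype=bool)
        edits["exclude"] = int(np.asarray(params.exclude_mask).sum())
    if params.include_mask is not None:
        mask = mask | np.asarray(params.include_mask, dtype=bool)
        edits["include"] = int(np.asarray(params.include_mask).sum())
    if not mask.any():
        raise NoLesionInWindowError(params.hu_low, params.hu_high)
    return LesionMask(
        voxels=mask,
        provenance={
            "hu_low": params.hu_low,
            "hu_high": params.hu_high,
            "connectivity": params.connectivity,
            "seed_point": params.seed_point,
            "fill_holes": params.fill_holes,
            "edits": edits,
        },
    )


def slice_areas(mask: LesionMask, volume: CTVolume) -> np.ndarray:
    """Per-slice haemorrhage area in cm^2 (zero on lesion-free slices)."""
    if not mask.voxels.any():
        raise ValueError("mask is empty")
    counts = mask.voxels.sum(axis=(1, 2))
    return counts * (volume.in_plane_spacing ** 2) / 100.0


def _outermost(polys: list[np.ndarray]) -> list[np.ndarray]:
    """Drop closed contours nested inside another contour (interior holes)."""
    if len(polys) <= 1:
        return polys
    from skimage.measure import points_in_poly

    keep = []
    for i, poly in enumerate(polys):
        inside = any(
            j != i and bool(points_in_poly(poly[:1], polys[j])[0])
            for j in range(len(polys))
        )
        if not inside:
            keep.append(poly)
    return keep


def slice_boundary_polygons(
    slice_mask: np.ndarray,
    spacing: float,
    slice_values: np.ndarray | None = None,
    level: float | None = None,
) -> list[np.ndarray]:
    """Sub-voxel outer boundary polygons (x, y in mm) of a lesion slice.

    When the HU image and a threshold level are given, the boundary is the
    iso-attenuation contour at that level: on partial-volume-rendered edges
    this interpolates the lesion outline to sub-voxel accuracy (the boundary
    an operator sees and traces).  Otherwise the marching-squares contour at
    the 0.5 level of the binary mask is used; that contour passes half a
    voxel outside the outermost voxel centres, so along any axis-aligned
    direction the extent is the count-based
    ``(max index - min index + 1) * spacing`` and a single voxel has extent
    one spacing, consistent with area = count x spacing^2.

    Interior hole contours are dropped: a planimetric ROI is the traced
    outline of the lesion.
    """
    from scipy.ndimage import binary_dilation
    from skimage.measure import find_contours

    polys: list[np.ndarray] = []
    if slice_values is not None and level is not None:
        near = binary_dilation(slice_mask, iterations=2)
        for contour in find_contours(slice_values, level):
            idx = np.clip(
                np.round(contour).astype(int), 0, np.array(slice_mask.shape) - 1
            )
            if near[idx[:, 0], idx[:, 1]].any():
                polys.append((contour[:, ::-1] + 0.5) * spacing)  # (col,row)->(x,y)
    if not polys:
        padded = np.pad(slice_mask.astype(float), 1)
        for contour in find_contours(padded, 0.5):
            polys.append((contour[:, ::-1] - 0.5) * spacing)
    return _outermost(polys)


def _slice_caliper(points_mm: np.ndarray) -> tuple[float, np.ndarray]:
    """Longest pairwise distance among boundary points and its direction."""
    pts = points_mm
    if len(pts) >= 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: brute force on all of them
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff ** 2).sum(axis=2)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    direction = pts[i] - pts[j]
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else np.array([1.0, 0.0])
    return float(math.sqrt(d2[i, j])), direction


def measure_A_B(
    mask: LesionMask, volume: CTVolume, level: float | None = None
) -> tuple[float, float, int]:
    """Longest axial diameter A, its same-slice perpendicular B (cm).

    Per slice the A candidate is the maximum pairwise distance between
    sub-voxel boundary points (rotating calipers over the convex hull of the
    boundary contour); A is the maximum over slices, ties broken toward the
    lower slice index.  B is the extent of the same slice's boundary
    projected onto the perpendicular of the A direction.

    The boundary is the iso-attenuation contour at ``level`` (defaulting to
    the segmentation's lower HU bound recorded in the mask provenance) where
    the image carries a partial-volume gradient, and the 0.5-level contour
    of the binary mask otherwise.
    """
    if not mask.voxels.any():
        raise ValueError("mask is empty")
    if level is None:
        level = mask.provenance.get("hu_low")
    sp = volume.in_plane_spacing
    best: tuple[float, int | None, tuple | None] = (-1.0, None, None)
    for k in range(mask.voxels.shape[0]):
        if not mask.voxels[k].any():
            continue
        polys = slice_boundary_polygons(
            mask.voxels[k], sp, volume.values[k] if level is not None else None, level
        )
        pts = np.concatenate(polys, axis=0)
        length, direction = _slice_caliper(pts)
        if length > best[0]:
            best = (length, k, (direction, pts))
    a_mm, a_slice, payload = best
    direction, pts = payload
    perp = np.array([-direction[1], direction[0]])
    proj = pts @ perp
    b_mm = float(proj.max() - proj.min())
    b_mm = min(b_mm, a_mm)  # discretisation can push the projection past A
    return a_mm / 10.0, b_mm / 10.0, int(a_slice)


def c_standard(mask: LesionMask, volume: CTVolume) -> float:
    """Craniocaudal extent C (cm): summed thickness of slices with lesion.

    With uniform slices this is thickness x number of slices showing any
    haemorrhage; summation is the natural generalisation when thickness
    varies through the series.
    """
    if not mask.voxels.any():
        raise ValueError("mask is empty")
    has_lesion = mask.voxels.any(axis=(1, 2))
    return float(volume.slice_thicknesses[has_lesion].sum()) / 10.0


def c_modified(areas_cm2: np.ndarray, thicknesses_mm: np.ndarray) -> float:
    """Area-weighted C (cm) for the modified ABC/2 method.

    Relative to the largest slice area: below 25 % a slice contributes
    nothing, above 75 % its full thickness, and between them (inclusive at
    both cut-offs) half its thickness.
    """
    areas = np.asarray(areas_cm2, dtype=float)
    thick = np.asarray(thicknesses_mm, dtype=float)
    if areas.shape != thick.shape:
        raise ValueError("areas and thicknesses must align per slice")
    max_area = areas.max()
    if max_area <= 0:
        raise ValueError("at least one slice area must be positive")
    weights = np.where(
        areas < 0.25 * max_area, 0.0, np.where(areas > 0.75 * max_area, 1.0, 0.5)
    )
    weights[areas <= 0] = 0.0
    return float((weights * thick).sum()) / 10.0


def abc2(triple: DiameterTriple) -> float:
    """The ellipsoid approximation A x B x C / 2 in cm^3."""
    return triple.A_cm * triple.B_cm * triple.C_cm / 2.0


def sas_volume(mask: LesionMask, volume: CTVolume) -> VolumeEstimate:
    """Planimetric volume: per-slice areas times slice thickness."""
    areas = slice_areas(mask, volume)  # cm^2
    vol = float((areas * volume.slice_thicknesses / 10.0).sum())
    return VolumeEstimate(method="sas", volume_cm3=vol)


def avc_volume(
    volume: CTVolume,
    params: SegmentationParams,
    allow_variable_thickness: bool = False,
) -> VolumeEstimate:
    """Seeded 3D region growing within the HU window (26-connectivity).

    Refuses series with varying slice thickness unless explicitly overridden,
    mirroring automatic tooling that assumes a uniform stack.  No hole
    filling or manual edits are applied: the method is fully automatic.
    """
    if params.seed_point is None:
        raise ValueError("avc_volume requires a seed_point")
    thick = volume.slice_thicknesses
    if not np.allclose(thick, thick[0]) and not allow_variable_thickness:
        raise VariableSliceThicknessError()
    window = (volume.values >= params.hu_low) & (volume.values <= params.hu_high)
    if not window.any():
        raise NoLesionInWindowError(params.hu_low, params.hu_high)
    grown = _component_mask(window, 26, params.seed_point)
    counts = grown.sum(axis=(1, 2))
    vol = float((counts * volume.in_plane_spacing ** 2 * thick).sum()) / 1000.0
    return VolumeEstimate(method="avc", volume_cm3=vol)


def measure_all(
    volume: CTVolume,
    params: SegmentationParams,
    include_avc: bool = False,
) -> dict[str, VolumeEstimate]:
    """Run every volumetry method on one scan with a shared segmentation."""
    mask = segment_threshold(volume, params)
    a_cm, b_cm, a_idx = measure_A_B(mask, volume)
    c_cm = c_standard(mask, volume)
    areas = slice_areas(mask, volume)
    c_mod_cm = c_modified(areas, volume.slice_thicknesses)
    triple = DiameterTriple(a_cm, b_cm, c_cm, a_idx)
    triple_mod = DiameterTriple(a_cm, b_cm, c_mod_cm, a_idx)
    out = {
        "abc2": VolumeEstimate("abc2", abc2(triple), triple),
        "modified_abc2": VolumeEstimate("modified_abc2", abc2(triple_mod), triple_mod),
        "sas": sas_volume(mask, volume),
    }
    if include_avc:
        seed = params.seed_point
        if seed is None:
            idx = np.argwhere(mask.voxels)
            seed = tuple(int(v) for v in idx[len(idx) // 2])
        out["avc"] = avc_volume(volume, replace(params, seed_point=seed))
    return out


def size_category(longest_diameter_cm: float) -> str:
    """Ordinal size category from the longest diameter in any plane.

    Bins: [0, 3), [3, 5), [5, 8], (8, inf); 5.0 falls in "5-8" because the
    printed categories 3-4.9 and 5-8 are adjacent and exhaustive.
    """
    if longest_diameter_cm <= 0:
        raise ValueError("diameter must be positive")
    if longest_diameter_cm < 3.0:
        return "<3"
    if longest_diameter_cm < 5.0:
        return "3-4.9"
    if longest_diameter_cm <= 8.0:
        return "5-8"
    return ">8"
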