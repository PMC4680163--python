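"""Synthetic CT phantoms with haematomas of known ground-truth volume.

Acute intracerebral haemorrhage is hyperattenuating on non-contrast CT
(roughly 40-80 HU) against brain parenchyma (roughly 25-35 HU).  This module
renders lesions of that kind onto a voxel grid so that measurement methods can
be evaluated against an analytic oracle:

* the lesion is a union of an axis-aligned (optionally in-plane rotated) core
  ellipsoid and ``n_lobes`` satellite ellipsoids centred on the core surface,
  giving a single irregularity knob with a computable oracle volume;
* voxels are rendered with partial-volume mixing: the HU of a voxel is the
  occupancy-weighted mixture of lesion and background HU, with occupancy
  estimated by 4x supersampling in every axis, so lesion boundaries blur the
  way real CT boundaries do;
* the ground-truth volume is computed by supersampled voxelisation of the
  analytic shape on a fine grid that is independent of the rendered grid.

Slice thickness is a per-slice vector: clinical CT series frequently change
thickness partway through the head (e.g. 4 mm posterior fossa, 8 mm vertex),
and that acquisition style matters to some volumetry methods.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull

from .ivh import VentricularState, GraebSchema, generate_ventricular_state

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CTVolume",
    "CohortConfig",
    "generate_phantom",
    "generate_cohort",
    "generate_ventricular_state",
    "variable_thickness_preset",
]

_SUPERSAMPLE = 4  # sub-voxel sampling factor per axis


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class CTVolume:
    """A CT-like image: HU values on a (slice, row, column) grid.

    Slice index 0 is the most inferior slice.  In-plane spacing is isotropic;
    through-plane spacing is carried per slice because it may vary within a
    series.
    """

    values: np.ndarray               # (n_slices, n_rows, n_cols), HU
    in_plane_spacing: float          # mm
    slice_thicknesses: np.ndarray    # mm, length n_slices

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float32)
        thick = np.asarray(self.slice_thicknesses, dtype=float)
        if values.ndim != 3:
            raise PhantomError("values must be a 3D (slice, row, column) array")
        if thick.ndim != 1 or thick.shape[0] != values.shape[0]:
            raise PhantomError(
                "slice_thicknesses must have one entry per slice "
                f"(got {thick.shape[0]} for {values.shape[0]} slices)"
            )
        if not np.all(np.isfinite(values)):
            raise PhantomError("values must be finite")
        if self.in_plane_spacing <= 0 or np.any(thick <= 0):
            raise PhantomError("spacing and slice thicknesses must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "slice_thicknesses", thick)

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def voxel_volumes_mm3(self) -> np.ndarray:
        """Per-slice voxel volume in mm^3."""
        return self.in_plane_spacing ** 2 * self.slice_thicknesses

    def slice_z_centres(self) -> np.ndarray:
        """Through-plane coordinate (mm) of each slice centre."""
        edges = np.concatenate([[0.0], np.cumsum(self.slice_thicknesses)])
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic haematoma phantom.

    ``ellipsoid_diameters`` is (axial-plane pair, through-plane) in mm.
    The grid is sized by ``grid_rows``/``grid_cols``/``slice_thicknesses``;
    ``centre`` positions the lesion in mm from the grid origin (corner of
    voxel (0, 0, 0)), ordered (x=column, y=row, z=through-plane).
    """

    ellipsoid_diameters: tuple[float, float, float]
    centre: tuple[float, float, float]
    grid_rows: int
    grid_cols: int
    slice_thicknesses: tuple[float, ...]
    in_plane_spacing: float = 1.0
    n_lobes: int = 0
    lobe_scale: float = 0.35
    lobe_centre_frac: float = 0.85
    rotation_deg: float = 0.0
    mean_hu: float = 65.0
    hetero_sd_hu: float = 0.0
    background_hu: float = 30.0
    noise_sd_hu: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.ellipsoid_diameters):
            raise PhantomError("all ellipsoid diameters must be positive")
        if self.mean_hu <= self.background_hu:
            raise PhantomError("lesion mean HU must exceed background HU")
        if not self.slice_thicknesses or any(t <= 0 for t in self.slice_thicknesses):
            raise PhantomError("slice thicknesses must be positive and non-empty")
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise PhantomError("grid must have positive size")
        if self.in_plane_spacing <= 0:
            raise PhantomError("in-plane spacing must be positive")
        if self.n_lobes < 0:
            raise PhantomError("n_lobes must be >= 0")
        if not 0 < self.lobe_scale < 1:
            raise PhantomError("lobe_scale must be in (0, 1)")
        if not 0 < self.lobe_centre_frac <= 1:
            raise PhantomError("lobe_centre_frac must be in (0, 1]")
        if self.hetero_sd_hu < 0 or self.noise_sd_hu < 0:
            raise PhantomError("noise/heterogeneity SDs must be >= 0")

    @property
    def shape_class(self) -> str:
        return "regular" if self.n_lobes == 0 else "irregular"


@dataclass(frozen=True)
class GroundTruth:
    """Oracle truth for a rendered phantom."""

    true_volume_cm3: float
    shape_class: str                 # {"regular", "irregular"}
    density_class: int               # ordinal 1-5 surrogate from hetero_sd/mean
    longest_diameter_cm: float       # maximal 3D extent of the analytic shape
    ventricular_state: VentricularState | None = None


@dataclass(frozen=True)
class _Ellipsoid:
    centre: np.ndarray      # (3,) mm, (x, y, z)
    semi_axes: np.ndarray   # (3,) mm
    rotation_deg: float     # in-plane rotation about z

    def inside_xy(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """In-plane quadratic form (ny, nx) from coordinate offsets."""
        theta = math.radians(self.rotation_deg)
        c, s = math.cos(theta), math.sin(theta)
        u = dx[None, :] * c + dy[:, None] * s
        v = -dx[None, :] * s + dy[:, None] * c
        return (u / self.semi_axes[0]) ** 2 + (v / self.semi_axes[1]) ** 2

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi) in mm."""
        theta = math.radians(self.rotation_deg)
        a, b, cz = self.semi_axes
        ex = math.hypot(a * math.cos(theta), b * math.sin(theta))
        ey = math.hypot(a * math.sin(theta), b * math.cos(theta))
        half = np.array([ex, ey, cz])
        return self.centre - half, self.centre + half

    def surface_points(self, n: int = 512) -> np.ndarray:
        """Quasi-uniform points on the surface (Fibonacci lattice)."""
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        golden = math.pi * (1 + 5 ** 0.5)
        theta = golden * i
        d = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
            axis=1,
        )
        pts = d * self.semi_axes
        rot = math.radians(self.rotation_deg)
        c, s = math.cos(rot), math.sin(rot)
        rotated = pts.copy()
        rotated[:, 0] = pts[:, 0] * c - pts[:, 1] * s
        rotated[:, 1] = pts[:, 0] * s + pts[:, 1] * c
        return rotated + self.centre

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Membership of (N, 3) points."""
        rel = pts - self.centre
        rot = math.radians(self.rotation_deg)
        c, s = math.cos(rot), math.sin(rot)
        u = rel[:, 0] * c + rel[:, 1] * s
        v = -rel[:, 0] * s + rel[:, 1] * c
        return (
            (u / self.semi_axes[0]) ** 2
            + (v / self.semi_axes[1]) ** 2
            + (rel[:, 2] / self.semi_axes[2]) ** 2
        ) <= 1.0


def _build_ellipsoids(spec: PhantomSpec, rng: np.random.Generator) -> list[_Ellipsoid]:
    semi = np.asarray(spec.ellipsoid_diameters, dtype=float) / 2.0
    core = _Ellipsoid(np.asarray(spec.centre, dtype=float), semi, spec.rotation_deg)
    shapes = [core]
    for _ in range(spec.n_lobes):
        # random direction; lobe centred near the core surface point along
        # it, partially embedded so lobes read as surface lumps rather than
        # detached satellites
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        # surface point in the core's rotated frame
        scale = 1.0 / math.sqrt(np.sum((d / semi) ** 2))
        local = d * scale * spec.lobe_centre_frac
        rot = math.radians(spec.rotation_deg)
        c, s = math.cos(rot), math.sin(rot)
        world = np.array(
            [local[0] * c - local[1] * s, local[0] * s + local[1] * c, local[2]]
        )
        lobe_semi = semi * spec.lobe_scale * rng.uniform(0.8, 1.2)
        shapes.append(
            _Ellipsoid(core.centre + world, lobe_semi, spec.rotation_deg)
        )
    return shapes


def _check_in_grid(shapes: Sequence[_Ellipsoid], spec: PhantomSpec) -> None:
    extent = np.array(
        [
            spec.grid_cols * spec.in_plane_spacing,
            spec.grid_rows * spec.in_plane_spacing,
            float(np.sum(spec.slice_thicknesses)),
        ]
    )
    lo = np.min([s.bbox()[0] for s in shapes], axis=0)
    hi = np.max([s.bbox()[1] for s in shapes], axis=0)
    for axis, name in enumerate(("x (column)", "y (row)", "z (slice)")):
        if lo[axis] < 0 or hi[axis] > extent[axis]:
            raise PhantomError(
                f"lesion extends outside the grid along axis {name}: "
                f"[{lo[axis]:.1f}, {hi[axis]:.1f}] mm vs grid [0, {extent[axis]:.1f}] mm"
            )


def _render_occupancy(shapes: Sequence[_Ellipsoid], spec: PhantomSpec) -> np.ndarray:
    """Per-voxel occupancy of the lesion union at 4x supersampling."""
    sp = spec.in_plane_spacing
    ss = _SUPERSAMPLE
    nx, ny = spec.grid_cols, spec.grid_rows
    xs = (np.arange(nx * ss) + 0.5) * (sp / ss)
    ys = (np.arange(ny * ss) + 0.5) * (sp / ss)
    edges = np.concatenate([[0.0], np.cumsum(spec.slice_thicknesses)])
    occ = np.empty((len(spec.slice_thicknesses), ny, nx), dtype=np.float32)

    # in-plane quadratic forms are z-independent (rotation is about z only),
    # so precompute them once per ellipsoid at the supersampled resolution
    forms = [
        (sh, sh.inside_xy(xs - sh.centre[0], ys - sh.centre[1])) for sh in shapes
    ]
    for k in range(len(spec.slice_thicknesses)):
        dz = (edges[k + 1] - edges[k]) / ss
        z_sub = edges[k] + (np.arange(ss) + 0.5) * dz
        inside = np.zeros((ss, ny * ss, nx * ss), dtype=bool)
        for sh, fxy in forms:
            zq = ((z_sub - sh.centre[2]) / sh.semi_axes[2]) ** 2
            np.logical_or(inside, fxy[None, :, :] + zq[:, None, None] <= 1.0, out=inside)
        occ[k] = (
            inside.reshape(ss, ny, ss, nx, ss).mean(axis=(0, 2, 4), dtype=np.float32)
        )
    return occ


def _oracle_volume_mm3(shapes: Sequence[_Ellipsoid], spec: PhantomSpec) -> float:
    """Union volume by fine-grid voxelisation independent of the render grid."""
    step_xy = spec.in_plane_spacing / _SUPERSAMPLE
    step_z = float(np.min(spec.slice_thicknesses)) / _SUPERSAMPLE
    lo = np.min([s.bbox()[0] for s in shapes], axis=0) - 1.0
    hi = np.max([s.bbox()[1] for s in shapes], axis=0) + 1.0
    xs = np.arange(lo[0] + step_xy / 2, hi[0], step_xy)
    ys = np.arange(lo[1] + step_xy / 2, hi[1], step_xy)
    zs = np.arange(lo[2] + step_z / 2, hi[2], step_z)
    count = 0
    block = max(1, int(4e6 // (len(xs) * len(ys))))
    forms = [(sh, sh.inside_xy(xs - sh.centre[0], ys - sh.centre[1])) for sh in shapes]
    for start in range(0, len(zs), block):
        zblk = zs[start : start + block]
        inside = np.zeros((len(zblk), len(ys), len(xs)), dtype=bool)
        for sh, fxy in forms:
            zq = ((zblk - sh.centre[2]) / sh.semi_axes[2]) ** 2
            np.logical_or(inside, fxy[None] + zq[:, None, None] <= 1.0, out=inside)
        count += int(inside.sum())
    return count * step_xy * step_xy * step_z


def _longest_diameter_mm(shapes: Sequence[_Ellipsoid]) -> float:
    """Maximal 3D extent of the union, from surface samples of each ellipsoid."""
    pts = []
    for i, sh in enumerate(shapes):
        p = sh.surface_points(512)
        keep = np.ones(len(p), dtype=bool)
        for j, other in enumerate(shapes):
            if i != j:
                keep &= ~other.contains(p)
        pts.append(p[keep])
    allpts = np.concatenate(pts, axis=0)
    if len(allpts) > 4:
        try:
            allpts = allpts[ConvexHull(allpts).vertices]
        except Exception:  # degenerate (coplanar) clouds fall back to all points
            pass
    diff = allpts[:, None, :] - allpts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).max())


def _density_class(hetero_sd_hu: float, mean_hu: float) -> int:
    """Ordinal 1-5 heterogeneity surrogate from the generating CV.

    Bins of width 0.05 in CV = hetero_sd/mean; purely a generator-side label
    standing in for visual density ratings, not calibrated to any reader study.
    """
    cv = hetero_sd_hu / mean_hu
    return 1 + min(4, int(cv / 0.05))


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Render a phantom and return it with its analytic ground truth.

    The rendered HU of a voxel is ``occ * lesion_hu + (1 - occ) * background``
    plus Gaussian acquisition noise, where ``occ`` is sub-voxel lesion
    occupancy and ``lesion_hu`` carries a spatially smoothed heterogeneity
    field of the requested SD.  Identical specs (including seed) produce
    bit-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    shapes = _build_ellipsoids(spec, rng)
    _check_in_grid(shapes, spec)

    occ = _render_occupancy(shapes, spec)

    lesion_hu = np.full(occ.shape, spec.mean_hu, dtype=np.float32)
    if spec.hetero_sd_hu > 0:
        white = rng.standard_normal(occ.shape).astype(np.float32)
        smooth = gaussian_filter(white, sigma=(1.0, 2.0, 2.0))
        # normalise against what a largest-slice ROI actually measures: the
        # heterogeneity reaching a voxel is occupancy-weighted, and smoothing
        # leaves each slice with less variance than the volume as a whole, so
        # scale the occupancy-weighted field to the requested SD on the
        # lesion-dominant voxels of the largest slice
        interior = occ > 0.5
        slice_counts = interior.sum(axis=(1, 2))
        k = int(np.argmax(slice_counts))
        contribution = (occ[k] * smooth[k])[interior[k]]
        sd = contribution.std() if contribution.size > 1 else smooth.std()
        if sd > 0:
            lesion_hu += smooth * (spec.hetero_sd_hu / sd)

    values = occ * lesion_hu + (1.0 - occ) * spec.background_hu
    if spec.noise_sd_hu > 0:
        values = values + rng.normal(0.0, spec.noise_sd_hu, occ.shape).astype(
            np.float32
        )

    volume = CTVolume(
        values=values.astype(np.float32),
        in_plane_spacing=spec.in_plane_spacing,
        slice_thicknesses=np.asarray(spec.slice_thicknesses, dtype=float),
    )
    truth = GroundTruth(
        true_volume_cm3=_oracle_volume_mm3(shapes, spec) / 1000.0,
        shape_class=spec.shape_class,
        density_class=_density_class(spec.hetero_sd_hu, spec.mean_hu),
        longest_diameter_cm=_longest_diameter_mm(shapes) / 10.0,
    )
    return volume, truth


def variable_thickness_preset(
    n_thin: int, n_thick: int, thin_mm: float = 4.0, thick_mm: float = 8.0
) -> tuple[float, ...]:
    """Slice-thickness vector for the thin-below/thick-above acquisition style."""
    return tuple([thin_mm] * n_thin + [thick_mm] * n_thick)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Size-category proportions of the emulated cohort: fractions of lesions with
#: longest visual diameter <3, 3-4.9, 5-8 and >8 cm.
DEFAULT_SIZE_PROPORTIONS = (0.41, 0.41, 0.16, 0.02)

#: Diameter range (cm) sampled within each size category.
SIZE_CATEGORY_RANGES_CM = ((1.5, 3.0), (3.0, 4.9), (5.0, 8.0), (8.0, 9.5))


@dataclass(frozen=True)
class CohortConfig:
    """Distributional description of a phantom cohort.

    Defaults emulate a clinically realistic acute ICH case-mix: ~40/40/16/2 %
    across the <3 / 3-4.9 / 5-8 / >8 cm longest-diameter categories and a
    64 % irregular-shape fraction.
    """

    n: int = 100
    size_proportions: tuple[float, float, float, float] = DEFAULT_SIZE_PROPORTIONS
    #: P(irregular shape) per size category; larger haematomas are more often
    #: irregular, and the default case-mix lands the overall irregular
    #: fraction near 64 %
    irregular_fraction_by_category: tuple[float, float, float, float] = (
        0.50,
        0.65,
        0.85,
        0.95,
    )
    lobe_range: tuple[int, int] = (2, 4)
    lobe_scale_range: tuple[float, float] = (0.25, 0.4)
    lobe_centre_frac: float = 0.85
    axis_ratio_range: tuple[float, float] = (0.6, 0.9)
    mean_hu: float = 65.0
    hetero_sd_range_hu: tuple[float, float] = (0.0, 12.0)
    background_hu: float = 30.0
    noise_sd_hu: float = 4.0
    slice_thickness_mm: float = 4.0
    in_plane_spacing_mm: float = 1.0
    margin_mm: float = 12.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise PhantomError("cohort size must be >= 0")
        total = sum(self.size_proportions)
        if abs(total - 1.0) > 1e-9:
            raise PhantomError(
                f"size-category proportions must sum to 1 (got {total:.4f})"
            )
        if any(not 0 <= f <= 1 for f in self.irregular_fraction_by_category):
            raise PhantomError("irregular fractions must be in [0, 1]")


def _spec_from_draw(cfg: CohortConfig, rng: np.random.Generator, seed: int) -> PhantomSpec:
    category = int(rng.choice(4, p=np.asarray(cfg.size_proportions)))
    lo, hi = SIZE_CATEGORY_RANGES_CM[category]
    d1 = rng.uniform(lo, hi) * 10.0  # mm
    d2 = d1 * rng.uniform(*cfg.axis_ratio_range)
    d3 = d1 * rng.uniform(*cfg.axis_ratio_range)
    irregular = rng.random() < cfg.irregular_fraction_by_category[category]
    n_lobes = int(rng.integers(cfg.lobe_range[0], cfg.lobe_range[1] + 1)) if irregular else 0
    lobe_scale = float(rng.uniform(*cfg.lobe_scale_range))
    hetero = float(rng.uniform(*cfg.hetero_sd_range_hu))
    rotation = float(rng.uniform(0.0, 180.0))

    # size the grid generously: lobes can extend the core by ~lobe_scale * d
    reach = 0.5 * d1 * (1.0 + (lobe_scale if n_lobes else 0.0) * 1.3) + cfg.margin_mm
    side_mm = 2.0 * reach
    n_inplane = int(math.ceil(side_mm / cfg.in_plane_spacing_mm))
    n_slices = int(math.ceil(side_mm / cfg.slice_thickness_mm))
    centre = (
        n_inplane * cfg.in_plane_spacing_mm / 2.0,
        n_inplane * cfg.in_plane_spacing_mm / 2.0,
        n_slices * cfg.slice_thickness_mm / 2.0,
    )
    return PhantomSpec(
        ellipsoid_diameters=(d1, d2, d3),
        centre=centre,
        grid_rows=n_inplane,
        grid_cols=n_inplane,
        slice_thicknesses=(cfg.slice_thickness_mm,) * n_slices,
        in_plane_spacing=cfg.in_plane_spacing_mm,
        n_lobes=n_lobes,
        lobe_scale=lobe_scale,
        lobe_centre_frac=cfg.lobe_centre_frac,
        rotation_deg=rotation,
        mean_hu=cfg.mean_hu,
        hetero_sd_hu=hetero,
        background_hu=cfg.background_hu,
        noise_sd_hu=cfg.noise_sd_hu,
        seed=seed,
    )


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[list[tuple[CTVolume, GroundTruth]], "pandas.DataFrame"]:
    """Draw a cohort of phantoms; returns scans and a manifest table.

    A pure function of (config, seed): the manifest and every volume are
    reproducible bit-for-bit.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    phantom_seeds = rng.integers(0, 2**31 - 1, size=config.n)
    scans: list[tuple[CTVolume, GroundTruth]] = []
    rows = []
    for i in range(config.n):
        spec = _spec_from_draw(config, rng, int(phantom_seeds[i]))
        vol, truth = generate_phantom(spec)
        scans.append((vol, truth))
        row = {"scan_id": f"phantom_{i:04d}"}
        row.update(
            {
                "diam_x_mm": spec.ellipsoid_diameters[0],
                "diam_y_mm": spec.ellipsoid_diameters[1],
                "diam_z_mm": spec.ellipsoid_diameters[2],
                "n_lobes": spec.n_lobes,
                "lobe_scale": spec.lobe_scale,
                "rotation_deg": spec.rotation_deg,
                "mean_hu": spec.mean_hu,
                "hetero_sd_hu": spec.hetero_sd_hu,
                "background_hu": spec.background_hu,
                "noise_sd_hu": spec.noise_sd_hu,
                "in_plane_spacing_mm": spec.in_plane_spacing,
                "slice_thickness_mm": config.slice_thickness_mm,
                "seed": spec.seed,
                "true_volume_cm3": truth.true_volume_cm3,
                "shape_class": truth.shape_class,
                "density_class": truth.density_class,
                "longest_diameter_cm": truth.longest_diameter_cm,
            }
        )
        rows.append(row)
    manifest = pd.DataFrame(
        rows,
        columns=[
            "scan_id", "diam_x_mm", "diam_y_mm", "diam_z_mm", "n_lobes",
            "lobe_scale", "rotation_deg", "mean_hu", "hetero_sd_hu",
            "background_hu", "noise_sd_hu", "in_plane_spacing_mm",
            "slice_thickness_mm", "seed", "true_volume_cm3", "shape_class",
            "density_class", "longest_diameter_cm",
        ],
    )
    return scans, manifest
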