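"""Characterization of fabricated beam modifiers from CT scans and
point measurements.

Covers the quality-assurance computations used to qualify a printed
bolus or compensator against its design: subpixel iso-contour
extraction from CT slices, the per-slice largest Euclidean
design-to-print distance (a symmetric Hausdorff metric on sampled
contour points), Hounsfield-unit uniformity with interface erosion,
mass density from weight and design volume, height-gauge point checks,
and a user-calibrated HU to relative-electron-density mapping.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage import measure

from .formats import CTVolume
from .geometry import (
    ConformityReport,
    Contour,
    ContourError,
    ContourStack,
    TriangleMesh,
    contour_at,
    mesh_volume,
    resample_contour,
)

__all__ = [
    "extract_slice_profile",
    "slice_conformity",
    "conformity_report",
    "hu_stats",
    "estimate_density",
    "height_check",
    "hu_to_red",
    "HeightCheck",
]


# ---------------------------------------------------------------------------
# CT profile extraction
# ---------------------------------------------------------------------------


def default_threshold(hu_slice: np.ndarray) -> float:
    """Midpoint between background and material mean HU.

    One two-means split: voxels are divided at the global mid-range and
    the threshold is the midpoint of the two class means.
    """
    cut = 0.5 * (float(hu_slice.min()) + float(hu_slice.max()))
    lo = hu_slice[hu_slice <= cut]
    hi = hu_slice[hu_slice > cut]
    if len(lo) == 0 or len(hi) == 0:
        raise ValueError("slice has a single intensity class; no object present")
    return 0.5 * (float(lo.mean()) + float(hi.mean()))


def extract_slice_profile(
    v: CTVolume, z_mm: float, threshold_hu: float = None
) -> Contour:
    """Subpixel iso-contour of the object on the axial slice at z_mm.

    Marching squares with linear interpolation at ``threshold_hu``
    (default: midpoint between background and material mean HU).  If
    several closed components exist, the largest-area one is returned
    with a warning.  Coordinates are patient mm.
    """
    iz = v.slice_index(z_mm)
    hu = np.asarray(v.hu[iz], dtype=float)
    if threshold_hu is None:
        threshold_hu = default_threshold(hu)
    raw = measure.find_contours(hu, level=threshold_hu)
    closed = [c for c in raw if np.allclose(c[0], c[-1]) and len(c) >= 4]
    if not closed:
        raise ValueError(
            f"no closed iso-contour at {threshold_hu:.1f} HU on slice z={z_mm} mm"
        )

    def shoelace(c):
        y, x = c[:, 0], c[:, 1]
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    areas = [shoelace(c) for c in closed]
    if len(closed) > 1:
        warnings.warn(
            f"{len(closed)} closed components on slice z={z_mm} mm; "
            "returning the largest"
        )
    c = closed[int(np.argmax(areas))][:-1]  # drop duplicated closing point
    sx, sy, _ = v.spacing_mm
    x = v.origin_mm[0] + c[:, 1] * sx
    y = v.origin_mm[1] + c[:, 0] * sy
    return Contour(float(v.z_positions()[iz]), np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# Geometric conformity
# ---------------------------------------------------------------------------


def slice_conformity(design: Contour, measured: Contour) -> float:
    """Largest Euclidean distance between two sampled contours.

    Symmetric Hausdorff metric on the sampled points: the maximum over
    the points of either contour of the distance to the nearest point
    of the other.  Both contours should be resampled to <= 0.5 mm
    spacing first so the point-sampling error is bounded by 0.25 mm.
    """
    a, b = design.points, measured.points
    if len(a) == 0 or len(b) == 0:
        raise ContourError("empty contour")
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def _rigid_icp_2d(moving: np.ndarray, fixed: np.ndarray, n_iter: int = 30):
    """Rigid 2-D ICP (rotation + translation) of moving onto fixed."""
    from scipy.spatial import cKDTree

    tree = cKDTree(fixed)
    pts = moving.copy()
    total_r = np.eye(2)
    total_t = np.zeros(2)
    for _ in range(n_iter):
        _, idx = tree.query(pts)
        target = fixed[idx]
        mu_p, mu_t = pts.mean(axis=0), target.mean(axis=0)
        h = (pts - mu_p).T @ (target - mu_t)
        u, _, vt = np.linalg.svd(h)
        r = (u @ vt).T
        if np.linalg.det(r) < 0:
            vt[-1] *= -1
            r = (u @ vt).T
        t = mu_t - r @ mu_p
        new = pts @ r.T + t
        if np.max(np.linalg.norm(new - pts, axis=1)) < 1e-6:
            pts = new
            total_r = r @ total_r
            total_t = r @ total_t + t
            break
        pts = new
        total_r = r @ total_r
        total_t = r @ total_t + t
    return pts, total_r, total_t


def conformity_report(
    design: ContourStack,
    measured: ContourStack,
    register: bool = False,
    resample_mm: float = 0.5,
) -> ConformityReport:
    """Per-slice largest Euclidean distance between a design and a
    measured (CT-extracted) contour stack, with mean and population
    standard deviation over slices.

    For every measured slice inside the design z range, the design
    contour is linearly interpolated to the measured z, both contours
    are resampled to <= ``resample_mm`` spacing, and the symmetric
    largest nearest-point distance is recorded.  With ``register`` a
    rigid 2-D pre-registration (centroid translation + ICP, pooled over
    slices) is applied to the measured stack first and recorded.
    """
    dz0, dz1 = design.z_mm[0], design.z_mm[-1]
    common = [c for c in measured if dz0 - 1e-9 <= c.z_mm <= dz1 + 1e-9]
    if not common:
        raise ContourError("design and measured stacks share no z range")

    pairs = []
    for mc in common:
        dc = contour_at(design, mc.z_mm)
        pairs.append(
            (
                resample_contour(dc, resample_mm),
                resample_contour(mc, resample_mm),
            )
        )

    registration = {}
    if register:
        fixed = np.vstack([d.points for d, _ in pairs])
        moving = np.vstack([m.points for _, m in pairs])
        shift = fixed.mean(axis=0) - moving.mean(axis=0)
        _, rot, trans = _rigid_icp_2d(moving + shift, fixed)
        registration = {
            "pre_shift_mm": [float(s) for s in shift],
            "rotation": [[float(x) for x in row] for row in rot],
            "translation_mm": [float(t) for t in trans],
        }
        new_pairs = []
        for d, m in pairs:
            pts = (m.points + shift) @ rot.T + trans
            new_pairs.append((d, Contour(m.z_mm, pts)))
        pairs = new_pairs

    per_slice = [
        (m.z_mm, slice_conformity(d, m)) for d, m in pairs
    ]
    dist = np.array([d for _, d in per_slice])
    return ConformityReport(
        per_slice_mm=per_slice,
        mean_mm=float(dist.mean()),
        sd_mm=float(dist.std()),  # population sd
        registered=register,
        registration=registration,
    )


# ---------------------------------------------------------------------------
# HU uniformity and material properties
# ---------------------------------------------------------------------------


def hu_stats(
    v: CTVolume, object_mask: np.ndarray, erosion_margin_mm: float = 1.25
) -> tuple:
    """Mean and standard deviation HU inside a mask eroded away from the
    air/object interfaces.

    The mask is eroded by a Euclidean ball of radius
    ``erosion_margin_mm`` (anisotropic voxel spacing respected via a
    physically sampled distance transform) so partial-volume voxels at
    the interface do not bias the statistics.  Returns (mean, sd) with
    population sd.
    """
    mask = np.asarray(object_mask, dtype=bool)
    if mask.shape != v.hu.shape:
        raise ValueError("mask shape must match the CT volume")
    if erosion_margin_mm < 0:
        raise ValueError("erosion margin must be nonnegative")
    if erosion_margin_mm > 0:
        sx, sy, sz = v.spacing_mm
        depth = ndimage.distance_transform_edt(mask, sampling=(sz, sy, sx))
        mask = depth > erosion_margin_mm
    if not mask.any():
        raise ValueError(
            f"mask vanished after {erosion_margin_mm} mm erosion; "
            "use a smaller margin"
        )
    vals = np.asarray(v.hu, dtype=float)[mask]
    return float(vals.mean()), float(vals.std())


def threshold_mask(v: CTVolume, threshold_hu: float = None) -> np.ndarray:
    """Binary object mask by HU thresholding (largest connected
    component)."""
    hu = np.asarray(v.hu, dtype=float)
    if threshold_hu is None:
        threshold_hu = default_threshold(hu)
    mask = hu >= threshold_hu
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no voxels above threshold")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def estimate_density(mass_g: float, design_mesh: TriangleMesh) -> float:
    """Mass density in g/cm^3 from measured weight and design volume."""
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    vol_mm3 = mesh_volume(design_mesh)
    if vol_mm3 <= 0:
        raise ValueError("design mesh volume must be positive")
    return float(mass_g / (vol_mm3 / 1000.0))


# ---------------------------------------------------------------------------
# Height-gauge point checks
# ---------------------------------------------------------------------------


class HeightCheck:
    """Result of one height-gauge probe against the design."""

    def __init__(self, point_mm, design_mm, measured_mm):
        self.point_mm = tuple(float(p) for p in point_mm)
        self.design_mm = float(design_mm)
        self.measured_mm = float(measured_mm)

    @property
    def deviation_mm(self) -> float:
        return self.measured_mm - self.design_mm

    def to_dict(self) -> dict:
        return {
            "point_mm": list(self.point_mm),
            "design_mm": self.design_mm,
            "measured_mm": self.measured_mm,
            "deviation_mm": self.deviation_mm,
        }


def height_check(
    design, probes, measured_heights, tolerance_mm: float = 1.0
) -> tuple:
    """Compare gauge-measured heights at probe points with the design.

    ``design`` is a CompensatorGrid; the design height (base + thickness)
    is bilinearly interpolated at each planar probe position, which is
    exact for locally linear height fields.  Returns
    (list of HeightCheck, all_within_tolerance).
    """
    from scipy.interpolate import RegularGridInterpolator

    from .geometry import CompensatorGrid

    if not isinstance(design, CompensatorGrid):
        raise TypeError("height_check expects a CompensatorGrid design")
    probes = np.atleast_2d(np.asarray(probes, dtype=float))
    measured_heights = np.atleast_1d(np.asarray(measured_heights, dtype=float))
    if len(probes) != len(measured_heights):
        raise ValueError("one measured height per probe point required")
    sr, sc = design.pixel_spacing_mm
    ox, oy = design.origin_mm
    xs = ox + np.arange(design.n_cols) * sc
    ys = oy + np.arange(design.n_rows) * sr
    h = design.thickness_mm + design.base_thickness_mm
    interp = RegularGridInterpolator(
        (ys, xs), h, method="linear", bounds_error=True
    )
    checks = []
    for (px, py), meas in zip(probes, measured_heights):
        try:
            dh = float(interp((py, px)))
        except ValueError as exc:
            raise ValueError(
                f"probe ({px}, {py}) outside the compensator footprint"
            ) from exc
        checks.append(HeightCheck((px, py), dh, meas))
    ok = all(abs(c.deviation_mm) < tolerance_mm for c in checks)
    return checks, ok


# ---------------------------------------------------------------------------
# HU -> relative electron density calibration
# ---------------------------------------------------------------------------


def hu_to_red(calibration_table, hu) -> np.ndarray:
    """Relative electron density from a user-supplied piecewise-linear
    scanner calibration.

    ``calibration_table`` is a sequence of (HU, RED) nodes with HU
    strictly ascending (at least 2).  Values beyond the table ends are
    clamped with a warning; no default table is shipped because the
    mapping is scanner-specific.
    """
    table = np.asarray(calibration_table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or len(table) < 2:
        raise ValueError("calibration table needs >= 2 (HU, RED) rows")
    if np.any(np.diff(table[:, 0]) <= 0):
        raise ValueError("calibration HU nodes must be strictly ascending")
    hu_arr = np.asarray(hu, dtype=float)
    if np.any(hu_arr < table[0, 0]) or np.any(hu_arr > table[-1, 0]):
        warnings.warn(
            "HU outside the calibration range; clamping to the table ends"
        )
    out = np.interp(hu_arr, table[:, 0], table[:, 1])
    return float(out) if np.isscalar(hu) or hu_arr.ndim == 0 else out
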