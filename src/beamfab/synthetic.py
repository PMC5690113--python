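"""Synthetic fixtures: parametric bolus/compensator designs, simulated
CT scans of "printed" objects, and minimal DICOM fixture files.

Every pipeline input can be generated here so the whole tool chain runs
without patient data or physical prints.  All stochastic generators
require an explicit seed and are deterministic under it.  Generator
outputs are quantised to 1e-6 mm so DICOM decimal-string round trips
are exact.

Default imaging parameters emulate the characterization scans: 0.625 mm
CT slice spacing, PLA-like material at 130.1 +/- 10.1 HU or
polyamide-like at -72.1 +/- 5.3 HU against -1000 HU air, a small
Gaussian point-spread blur, and i.i.d. scanner noise added after the
blur so interior statistics keep the nominal standard deviation.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .formats import CT_SOP_CLASS, CTVolume, ION_PLAN_SOP_CLASS, RTSTRUCT_SOP_CLASS
from .geometry import CompensatorGrid, Contour, ContourStack, TriangleMesh

__all__ = [
    "FixtureSpec",
    "make_scalp_bolus",
    "make_compensator",
    "make_box_mesh",
    "make_cone_stack",
    "voxelize_ct",
    "write_fixture_dicoms",
    "write_rtstruct",
    "write_ion_plan",
    "write_ct_series",
]

# Printed-material HU regimes used as generator defaults
PLA_HU = (130.1, 10.1)
POLYAMIDE_HU = (-72.1, 5.3)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture and its simulated CT scan."""

    kind: str = "cube"
    params: dict = field(default_factory=dict)  # geometry, mm
    material_hu_mean: float = PLA_HU[0]
    material_hu_sd: float = PLA_HU[1]
    background_hu: float = -1000.0
    spacing_mm: tuple = (0.5, 0.5, 0.625)
    psf_sigma_mm: float = 0.4
    supersample: int = 1
    padding_mm: float = 5.0
    seed: int = None


def _q(x):
    """Quantise coordinates to 1e-6 mm (exact DICOM DS round trip)."""
    return np.round(np.asarray(x, dtype=float), 6)


# ---------------------------------------------------------------------------
# Parametric designs
# ---------------------------------------------------------------------------


def make_scalp_bolus(spec: FixtureSpec = None, seed: int = None) -> ContourStack:
    """Crescent-shaped scalp-like bolus as a stack of simple contours.

    Each axial slice is a band between an outer ellipse arc and an
    inward offset of it (uniform shell thickness), tapered along z and
    perturbed by seeded low-order harmonics to emulate an anatomy-fitted
    design.  Default extent ~40 mm in z with design slices every 2.5 mm.
    """
    spec = spec or FixtureSpec(kind="scalp_bolus")
    if seed is None:
        seed = spec.seed
    p = {
        "semi_axis_x_mm": 70.0,
        "semi_axis_y_mm": 55.0,
        "shell_thickness_mm": 12.0,
        "z_extent_mm": 40.0,
        "slice_spacing_mm": 2.5,
        "theta_start_deg": -20.0,
        "theta_end_deg": 200.0,
        "n_arc_points": 72,
        "perturbation_mm": 2.0,
        "taper": 0.15,
    }
    p.update(spec.params)
    rng = np.random.default_rng(seed if seed is not None else 0)
    amp = p["perturbation_mm"]
    n_harm = 3
    amps = amp * rng.uniform(0.3, 1.0, n_harm)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    z_phase = rng.uniform(0, 2 * np.pi)

    a, b = p["semi_axis_x_mm"], p["semi_axis_y_mm"]
    th = np.linspace(
        math.radians(p["theta_start_deg"]),
        math.radians(p["theta_end_deg"]),
        p["n_arc_points"],
    )
    zs = np.arange(0.0, p["z_extent_mm"] + 1e-9, p["slice_spacing_mm"])
    zc = p["z_extent_mm"] / 2.0
    contours = []
    for z in zs:
        taper = 1.0 - p["taper"] * ((z - zc) / max(zc, 1e-9)) ** 2
        r_ell = (a * taper) * (b * taper) / np.sqrt(
            (b * taper * np.cos(th)) ** 2 + (a * taper * np.sin(th)) ** 2
        )
        perturb = sum(
            amps[k]
            * np.cos((k + 1) * th + phases[k])
            * np.cos(np.pi * (z - zc) / p["z_extent_mm"] + z_phase)
            for k in range(n_harm)
        )
        r_out = r_ell + perturb
        r_in = r_out - p["shell_thickness_mm"]
        outer = np.column_stack([r_out * np.cos(th), r_out * np.sin(th)])
        inner = np.column_stack([r_in * np.cos(th), r_in * np.sin(th)])[::-1]
        pts = _q(np.vstack([outer, inner]))
        contours.append(Contour(float(_q(z)), pts))
    stack = ContourStack(contours)
    for c in stack:
        if not c.is_simple():
            raise ValueError(
                "generated bolus contour self-intersects; reduce perturbation"
            )
    return stack


def make_compensator(spec: FixtureSpec = None, seed: int = None) -> CompensatorGrid:
    """Concave proton compensator height field at 1 mm grid resolution.

    Thickness = uniform base + radial bowl (centre thinner than edge,
    shaping dose to a convex distal target surface) + seeded
    band-limited noise, clipped nonnegative.
    """
    from scipy.ndimage import zoom

    spec = spec or FixtureSpec(kind="compensator")
    if seed is None:
        seed = spec.seed
    p = {
        "n_rows": 81,
        "n_cols": 81,
        "pixel_spacing_mm": (1.0, 1.0),
        "base_thickness_mm": 20.0,
        "bowl_depth_mm": 15.0,
        "noise_mm": 1.0,
        "noise_cells": 7,
    }
    p.update(spec.params)
    rng = np.random.default_rng(seed if seed is not None else 0)
    R, C = p["n_rows"], p["n_cols"]
    r = (np.arange(R) - (R - 1) / 2)[:, None] * p["pixel_spacing_mm"][0]
    c = (np.arange(C) - (C - 1) / 2)[None, :] * p["pixel_spacing_mm"][1]
    rho2 = r**2 + c**2
    rho2_max = rho2.max()
    bowl = p["bowl_depth_mm"] * rho2 / rho2_max  # 0 at centre, max at corner
    coarse = rng.standard_normal((p["noise_cells"], p["noise_cells"]))
    noise = zoom(coarse, (R / p["noise_cells"], C / p["noise_cells"]), order=3)
    noise = p["noise_mm"] * noise[:R, :C]
    thickness = np.clip(p["base_thickness_mm"] + bowl + noise, 0.0, None)
    ox = -(C - 1) / 2 * p["pixel_spacing_mm"][1]
    oy = -(R - 1) / 2 * p["pixel_spacing_mm"][0]
    return CompensatorGrid(
        thickness_mm=_q(thickness),
        pixel_spacing_mm=p["pixel_spacing_mm"],
        origin_mm=(float(_q(ox)), float(_q(oy))),
    )


def make_box_mesh(size_mm, origin_mm=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Axis-aligned closed box of 12 outward-oriented facets."""
    s = np.broadcast_to(np.asarray(size_mm, dtype=float), (3,))
    o = np.asarray(origin_mm, dtype=float)
    corners = o + s * np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    facets = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (-z)
            [4, 5, 6], [4, 6, 7],  # top (+z)
            [0, 1, 5], [0, 5, 4],  # -y
            [2, 3, 7], [2, 7, 6],  # +y
            [1, 2, 6], [1, 6, 5],  # +x
            [3, 0, 4], [3, 4, 7],  # -x
        ]
    )
    return TriangleMesh(corners, facets)


def make_cone_stack(
    r_bottom_mm: float = 10.0,
    r_top_mm: float = 0.5,
    height_mm: float = 20.0,
    n_slices: int = 9,
    n_points: int = 64,
) -> ContourStack:
    """Stack of circles tapering linearly (a conical frustum)."""
    th = np.arange(n_points) / n_points * 2 * np.pi
    contours = []
    for i, z in enumerate(np.linspace(0.0, height_mm, n_slices)):
        r = r_bottom_mm + (r_top_mm - r_bottom_mm) * z / height_mm
        pts = _q(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        contours.append(Contour(float(_q(z)), pts))
    return ContourStack(contours)


# ---------------------------------------------------------------------------
# CT simulation
# ---------------------------------------------------------------------------


def _column_parity_mask(mesh: TriangleMesh, xs, ys, zs) -> np.ndarray:
    """Inside/outside classification of voxel centres by vertical-ray
    parity against the (watertight) mesh surface.

    Ray positions carry distinct sub-micron per-axis offsets so rays do
    not pass exactly through mesh edges or vertices of grid-aligned
    fixtures.
    """
    nx, ny, nz = len(xs), len(ys), len(zs)
    rx = np.asarray(xs) + 3.7e-5
    ry = np.asarray(ys) + 6.1e-5
    tri = mesh.triangles()
    cols_out, z_out = [], []
    for p0, p1, p2 in tri:
        area2 = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (
            p2[0] - p0[0]
        )
        if abs(area2) < 1e-12:
            continue  # vertical facet: no vertical-ray crossing
        x_min = min(p0[0], p1[0], p2[0])
        x_max = max(p0[0], p1[0], p2[0])
        y_min = min(p0[1], p1[1], p2[1])
        y_max = max(p0[1], p1[1], p2[1])
        ix0 = int(np.searchsorted(rx, x_min))
        ix1 = int(np.searchsorted(rx, x_max))
        iy0 = int(np.searchsorted(ry, y_min))
        iy1 = int(np.searchsorted(ry, y_max))
        if ix0 >= ix1 and iy0 >= iy1 and (ix0 >= nx or iy0 >= ny):
            continue
        qx = rx[ix0:ix1]
        qy = ry[iy0:iy1]
        if len(qx) == 0 or len(qy) == 0:
            continue
        QX, QY = np.meshgrid(qx, qy, indexing="ij")
        s0 = (p1[0] - p0[0]) * (QY - p0[1]) - (p1[1] - p0[1]) * (QX - p0[0])
        s1 = (p2[0] - p1[0]) * (QY - p1[1]) - (p2[1] - p1[1]) * (QX - p1[0])
        s2 = (p0[0] - p2[0]) * (QY - p2[1]) - (p0[1] - p2[1]) * (QX - p2[0])
        sgn = 1.0 if area2 > 0 else -1.0
        inside = (sgn * s0 > 0) & (sgn * s1 > 0) & (sgn * s2 > 0)
        if not inside.any():
            continue
        u = sgn * s1 / abs(area2)
        v = sgn * s2 / abs(area2)
        w = 1.0 - u - v
        zq = u * p0[2] + v * p1[2] + w * p2[2]
        ii, jj = np.nonzero(inside)
        cols_out.append((iy0 + jj) * nx + (ix0 + ii))
        z_out.append(zq[inside])
    mask = np.zeros((nz, ny, nx), dtype=bool)
    if not cols_out:
        return mask
    cols = np.concatenate(cols_out)
    zv = np.concatenate(z_out)
    order = np.lexsort((zv, cols))
    cols, zv = cols[order], zv[order]
    # parity index within each column run
    new_col = np.ones(len(cols), dtype=bool)
    new_col[1:] = cols[1:] != cols[:-1]
    run_start = np.maximum.accumulate(np.where(new_col, np.arange(len(cols)), 0))
    parity = (np.arange(len(cols)) - run_start) % 2
    # drop unpaired final crossings (numerical grazing)
    run_len = np.diff(np.append(np.flatnonzero(new_col), len(cols)))
    odd_runs = run_len % 2 == 1
    last_of_run = np.zeros(len(cols), dtype=bool)
    ends = np.append(np.flatnonzero(new_col)[1:], len(cols)) - 1
    last_of_run[ends[odd_runs]] = True
    keep = ~last_of_run
    cols, zv, parity = cols[keep], zv[keep], parity[keep]

    zc = np.asarray(zs)
    k = np.searchsorted(zc, zv)
    diff = np.zeros((ny * nx, nz + 1), dtype=np.int16)
    enter = parity == 0
    np.add.at(diff, (cols[enter], k[enter]), 1)
    np.add.at(diff, (cols[~enter], k[~enter]), -1)
    filled = np.cumsum(diff[:, :-1], axis=1) > 0
    mask = filled.T.reshape(nz, ny, nx)
    return mask


def voxelize_ct(m: TriangleMesh, spec: FixtureSpec = None) -> CTVolume:
    """Simulate a CT scan of a printed object.

    Voxel centres are classified inside/outside the mesh by vertical-ray
    parity; inside voxels get the material HU, outside the background
    HU.  Optional partial-volume averaging (``supersample`` subvoxels
    per axis), a Gaussian point-spread blur, and i.i.d. Gaussian noise
    (added after the blur, so interior noise keeps its nominal sd) give
    realistic air/object interface ramps.  Final HU values are rounded
    to integers, as a scanner reports them.
    """
    spec = spec or FixtureSpec()
    if spec.seed is None and spec.material_hu_sd > 0:
        raise ValueError("an explicit seed is required for a noisy scan")
    sx, sy, sz = spec.spacing_mm
    lo, hi = m.bounds()
    pad = spec.padding_mm
    nx = int(np.ceil((hi[0] - lo[0] + 2 * pad) / sx))
    ny = int(np.ceil((hi[1] - lo[1] + 2 * pad) / sy))
    nz = int(np.ceil((hi[2] - lo[2] + 2 * pad) / sz))
    origin = (lo[0] - pad + sx / 2, lo[1] - pad + sy / 2, lo[2] - pad + sz / 2)

    s = max(1, int(spec.supersample))
    if s == 1:
        xs = origin[0] + np.arange(nx) * sx
        ys = origin[1] + np.arange(ny) * sy
        zs = origin[2] + np.arange(nz) * sz
        inside = _column_parity_mask(m, xs, ys, zs)
        frac = inside.astype(np.float32)
    else:
        fx, fy, fz = sx / s, sy / s, sz / s
        xs = origin[0] - sx / 2 + fx / 2 + np.arange(nx * s) * fx
        ys = origin[1] - sy / 2 + fy / 2 + np.arange(ny * s) * fy
        zs = origin[2] - sz / 2 + fz / 2 + np.arange(nz * s) * fz
        fine = _column_parity_mask(m, xs, ys, zs).astype(np.float32)
        frac = fine.reshape(nz, s, ny, s, nx, s).mean(axis=(1, 3, 5))

    hu = spec.background_hu + frac * (spec.material_hu_mean - spec.background_hu)
    if spec.psf_sigma_mm > 0:
        from scipy.ndimage import gaussian_filter

        hu = gaussian_filter(
            hu, sigma=(spec.psf_sigma_mm / sz, spec.psf_sigma_mm / sy,
                       spec.psf_sigma_mm / sx)
        )
    if spec.material_hu_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + spec.material_hu_sd * rng.standard_normal(hu.shape)
    hu = np.round(hu)
    return CTVolume(hu=hu, spacing_mm=(sx, sy, sz), origin_mm=origin)


# ---------------------------------------------------------------------------
# DICOM fixture writers
# ---------------------------------------------------------------------------

_UID_ROOT = "2.25.860101"
_FIXED_DATE = "20200101"


def _uid(*parts) -> str:
    return ".".join([_UID_ROOT] + [str(int(p)) for p in parts])


def _base_dataset(sop_class, sop_instance, modality) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    ds.Modality = modality
    ds.PatientName = "Fixture^Synthetic"
    ds.PatientID = "FIXTURE"
    ds.StudyInstanceUID = _uid(1)
    ds.StudyDate = _FIXED_DATE
    ds.StudyTime = "000000"
    return ds


def write_rtstruct(path, rois: dict) -> None:
    """Write a minimal RT Structure Set holding the given
    {roi_name: ContourStack} mapping."""
    ds = _base_dataset(RTSTRUCT_SOP_CLASS, _uid(2, 1), "RTSTRUCT")
    ds.SeriesInstanceUID = _uid(2)
    ds.StructureSetLabel = "SynthFixtures"
    ds.StructureSetDate = _FIXED_DATE
    ds.StructureSetTime = "000000"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, (name, stack) in enumerate(rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = _uid(3)
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for c in stack:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = c.n_points
            data = np.column_stack(
                [c.points, np.full(c.n_points, c.z_mm)]
            ).ravel()
            item.ContourData = [float(v) for v in _q(data)]
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)


def write_ion_plan(path, grid: CompensatorGrid, beam_name: str = "Beam1") -> None:
    """Write a minimal RT Ion Plan with one beam carrying the range
    compensator thickness grid."""
    ds = _base_dataset(ION_PLAN_SOP_CLASS, _uid(4, 1), "RTPLAN")
    ds.SeriesInstanceUID = _uid(4)
    ds.RTPlanLabel = "SynthComp"
    ds.RTPlanDate = _FIXED_DATE
    ds.RTPlanTime = "000000"
    beam = Dataset()
    beam.BeamName = beam_name
    beam.BeamNumber = 1
    comp = Dataset()
    comp.CompensatorNumber = 1
    comp.CompensatorRows = grid.n_rows
    comp.CompensatorColumns = grid.n_cols
    comp.CompensatorPixelSpacing = [float(v) for v in grid.pixel_spacing_mm]
    comp.CompensatorPosition = [float(v) for v in grid.origin_mm]
    comp.CompensatorThicknessData = [
        float(v) for v in _q(grid.thickness_mm.ravel())
    ]
    beam.IonRangeCompensatorSequence = [comp]
    ds.IonBeamSequence = [beam]
    ds.save_as(path, enforce_file_format=True)


def write_ct_series(directory, v: CTVolume) -> list:
    """Write a CT volume as one DICOM file per slice.

    HU must be integer-valued (scanner convention); stored as unsigned
    16-bit with rescale intercept -2048, which round-trips exactly.
    """
    os.makedirs(directory, exist_ok=True)
    hu = np.asarray(v.hu)
    if not np.allclose(hu, np.round(hu)):
        raise ValueError("CT fixture HU must be integer-valued")
    intercept = -2048.0
    raw = np.round(hu - intercept)
    if raw.min() < 0 or raw.max() > 65535:
        raise ValueError("HU out of the representable fixture range")
    raw = raw.astype(np.uint16)
    series_uid = _uid(5)
    paths = []
    for i in range(hu.shape[0]):
        ds = _base_dataset(CT_SOP_CLASS, _uid(5, 1, i), "CT")
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [
            float(v.origin_mm[0]),
            float(v.origin_mm[1]),
            float(v.origin_mm[2] + i * v.spacing_mm[2]),
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(v.spacing_mm[1]), float(v.spacing_mm[0])]
        ds.SliceThickness = float(v.spacing_mm[2])
        ds.Rows, ds.Columns = hu.shape[1], hu.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.PixelData = raw[i].tobytes()
        path = os.path.join(directory, f"ct_{i:04d}.dcm")
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_fixture_dicoms(objects: dict, directory) -> dict:
    """Write a set of fixtures to a directory.

    ``objects`` maps keys to fixtures: ContourStack values become ROIs
    of one RTSTRUCT, CompensatorGrid values become ion plans, CTVolume
    values become CT series subdirectories.  Returns {key: path}.
    """
    os.makedirs(directory, exist_ok=True)
    out = {}
    rois = {k: v for k, v in objects.items() if isinstance(v, ContourStack)}
    if rois:
        path = os.path.join(directory, "rtstruct.dcm")
        write_rtstruct(path, rois)
        for k in rois:
            out[k] = path
    for k, v in objects.items():
        if isinstance(v, CompensatorGrid):
            path = os.path.join(directory, f"ion_plan_{k}.dcm")
            write_ion_plan(path, v)
            out[k] = path
        elif isinstance(v, CTVolume):
            path = os.path.join(directory, f"ct_{k}")
            write_ct_series(path, v)
            out[k] = path
    return out
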