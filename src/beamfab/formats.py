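"""Readers and writers for the standard formats the pipeline touches:
DICOM RT Structure Set, DICOM RT Ion Plan (range compensator), DICOM CT
series and STL (binary and ASCII).

STL is unitless; this package always writes meshes in millimetres and
records the unit in the 80-byte header comment of binary files.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pydicom
import trimesh

from .geometry import CompensatorGrid, Contour, ContourError, ContourStack, TriangleMesh

__all__ = [
    "CTVolume",
    "read_rtstruct",
    "read_ion_plan_compensator",
    "read_ct_series",
    "write_stl",
    "read_stl",
]

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
ION_PLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.8"
CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"


class DicomFormatError(ValueError):
    """Raised when a DICOM file does not carry the expected objects."""


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units.

    hu         : (nz, ny, nx) array, rescale slope/intercept applied
    spacing_mm : (sx, sy, sz) voxel spacing
    origin_mm  : (x, y, z) of the centre of voxel [0, 0, 0]
    """

    hu: np.ndarray
    spacing_mm: tuple
    origin_mm: tuple

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise ValueError("CT volume must be 3-D (nz, ny, nx)")
        if min(self.spacing_mm) <= 0:
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self):
        return self.hu.shape

    def z_positions(self) -> np.ndarray:
        return self.origin_mm[2] + np.arange(self.hu.shape[0]) * self.spacing_mm[2]

    def slice_index(self, z_mm: float) -> int:
        """Index of the axial slice nearest to z_mm (must be in range)."""
        z = self.z_positions()
        i = int(np.argmin(np.abs(z - z_mm)))
        if abs(z[i] - z_mm) > self.spacing_mm[2] / 2 + 1e-6:
            raise ValueError(f"z={z_mm} mm outside the scanned volume")
        return i


# ---------------------------------------------------------------------------
# DICOM RT Structure Set
# ---------------------------------------------------------------------------


def read_rtstruct(path, roi_name: str) -> ContourStack:
    """Extract the named ROI from an RT Structure Set as a ContourStack.

    Contours are returned in patient millimetre coordinates, sorted
    ascending in z; a duplicated closing point in the file is dropped.
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "SOPClassUID", None) != RTSTRUCT_SOP_CLASS and not hasattr(
        ds, "StructureSetROISequence"
    ):
        raise DicomFormatError(f"{path} is not an RT Structure Set")
    names = {
        int(item.ROINumber): str(item.ROIName)
        for item in ds.StructureSetROISequence
    }
    matches = [num for num, name in names.items() if name == roi_name]
    if not matches:
        available = ", ".join(sorted(names.values()))
        raise DicomFormatError(
            f"ROI '{roi_name}' not found; available ROIs: {available}"
        )
    roi_number = matches[0]
    roi_contour = next(
        (
            item
            for item in ds.ROIContourSequence
            if int(item.ReferencedROINumber) == roi_number
        ),
        None,
    )
    if roi_contour is None or not getattr(roi_contour, "ContourSequence", None):
        raise DicomFormatError(f"ROI '{roi_name}' has no contour data")

    contours = []
    for item in roi_contour.ContourSequence:
        data = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
        z = data[:, 2]
        if np.ptp(z) > 1e-3:
            raise DicomFormatError(
                f"non-planar contour in ROI '{roi_name}' (z spread {np.ptp(z):.3g} mm)"
            )
        pts = data[:, :2]
        if len(pts) > 3 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        contours.append(Contour(float(z.mean()), pts))
    contours.sort(key=lambda c: c.z_mm)
    return ContourStack(contours)


# ---------------------------------------------------------------------------
# DICOM RT Ion Plan (range compensator)
# ---------------------------------------------------------------------------


def read_ion_plan_compensator(path, beam_index: int = 0) -> CompensatorGrid:
    """Read the range-compensator thickness grid of one beam of an RT
    Ion Plan.

    Thickness data is taken from the standard ion range compensator
    sequence row-major, in mm.
    """
    ds = pydicom.dcmread(path)
    beams = getattr(ds, "IonBeamSequence", None)
    if beams is None:
        raise DicomFormatError(f"{path} has no IonBeamSequence (not an ion plan?)")
    if not (0 <= beam_index < len(beams)):
        raise DicomFormatError(
            f"beam_index {beam_index} out of range (plan has {len(beams)} beams)"
        )
    beam = beams[beam_index]
    comps = getattr(beam, "IonRangeCompensatorSequence", None)
    if not comps:
        raise DicomFormatError(
            f"beam {beam_index} ('{getattr(beam, 'BeamName', '?')}') has no "
            "range compensator"
        )
    comp = comps[0]
    rows = int(comp.CompensatorRows)
    cols = int(comp.CompensatorColumns)
    spacing = tuple(float(v) for v in comp.CompensatorPixelSpacing)  # (row, col)
    position = tuple(float(v) for v in comp.CompensatorPosition)  # (x, y) of (0,0)
    thickness = np.asarray(comp.CompensatorThicknessData, dtype=float).reshape(
        rows, cols
    )
    return CompensatorGrid(
        thickness_mm=thickness,
        pixel_spacing_mm=spacing,
        origin_mm=position,
    )


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------


def read_ct_series(directory) -> CTVolume:
    """Load a single-series directory of CT slices into a CTVolume.

    Slices are sorted by patient z position regardless of file order;
    the rescale slope/intercept of each file is applied; z spacing must
    be uniform to 1e-3 mm.
    """
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if f.lower().endswith(".dcm")
    )
    if not files:
        raise DicomFormatError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    uids = {str(s.SeriesInstanceUID) for s in slices}
    if len(uids) != 1:
        raise DicomFormatError(f"mixed series in {directory}: {sorted(uids)}")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    z = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    dz = np.diff(z)
    if len(dz):
        if np.any(dz <= 0):
            raise DicomFormatError("duplicate slice positions in series")
        if np.ptp(dz) > 1e-3:
            raise DicomFormatError(
                f"non-uniform slice spacing: min {dz.min():.4f}, max {dz.max():.4f} mm"
            )
    first = slices[0]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)  # (y, x)
    sz = float(dz.mean()) if len(dz) else float(
        getattr(first, "SliceThickness", 1.0)
    )
    hu = np.stack(
        [
            s.pixel_array.astype(np.float64) * float(getattr(s, "RescaleSlope", 1.0))
            + float(getattr(s, "RescaleIntercept", 0.0))
            for s in slices
        ]
    )
    x0, y0 = (float(v) for v in first.ImagePositionPatient[:2])
    return CTVolume(
        hu=hu,
        spacing_mm=(col_sp, row_sp, sz),
        origin_mm=(x0, y0, float(z[0])),
    )


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------


def write_stl(m: TriangleMesh, path, mode: str = "binary") -> None:
    """Write a mesh as STL (binary by default, 'ascii' optional).

    Vertices are rounded to single precision before writing so binary
    and ASCII outputs re-read float32-identical.  Binary layout is the
    standard one: 80-byte header, little-endian uint32 facet count,
    50 bytes per facet with a zero attribute byte count.
    """
    if mode not in ("binary", "ascii"):
        raise ValueError("mode must be 'binary' or 'ascii'")
    verts32 = m.vertices.astype(np.float32).astype(np.float64)
    tm = trimesh.Trimesh(vertices=verts32, faces=m.facets, process=False)
    tm.metadata["name"] = "units=mm"
    if mode == "binary":
        data = trimesh.exchange.stl.export_stl(tm)
        # stamp the unit note into the 80-byte comment header
        header = b"beamfab units=mm".ljust(80, b" ")[:80]
        with open(path, "wb") as fh:
            fh.write(header + data[80:])
    else:
        text = trimesh.exchange.stl.export_stl_ascii(tm)
        with open(path, "w") as fh:
            fh.write(text)


def read_stl(path) -> TriangleMesh:
    """Read an STL file (binary or ASCII) into a TriangleMesh.

    STL stores an unindexed triangle soup; exactly coincident vertices
    are merged back into a shared vertex table so watertight topology
    survives a round trip.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    size = len(raw)
    is_ascii = raw[:5] == b"solid" and b"facet" in raw[:1000]
    if not is_ascii:
        if size < 84:
            raise DicomFormatError(f"{path}: truncated binary STL")
        n_facets = int(np.frombuffer(raw[80:84], dtype="<u4")[0])
        expected = 84 + 50 * n_facets
        if size != expected:
            raise DicomFormatError(
                f"{path}: corrupt binary STL — header declares {n_facets} "
                f"facets ({expected} bytes) but file is {size} bytes"
            )
    with open(path, "rb") as fh:
        loaded = trimesh.exchange.stl.load_stl(fh)
    tris = np.asarray(loaded["vertices"], dtype=np.float64)[
        np.asarray(loaded["faces"], dtype=np.int64)
    ].reshape(-1, 3)
    uniq, inverse = np.unique(tris, axis=0, return_inverse=True)
    facets = inverse.reshape(-1, 3)
    degenerate = (
        (facets[:, 0] == facets[:, 1])
        | (facets[:, 1] == facets[:, 2])
        | (facets[:, 2] == facets[:, 0])
    )
    if np.any(degenerate):
        warnings.warn(
            f"{path}: {int(degenerate.sum())} degenerate facet(s) dropped on read"
        )
        facets = facets[~degenerate]
    return TriangleMesh(uniq, facets)
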