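"""Core geometric types and operations for beam-modifier fabrication.

All coordinates are millimetres in the DICOM LPS patient frame
(x: right->left, y: anterior->posterior, z: inferior->superior).
Contours are closed planar polygons stored without a duplicated
closing vertex; meshes are triangle surfaces indexed into a shared
vertex table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np


class MeshError(ValueError):
    """Raised when a mesh violates a precondition (e.g. not watertight)."""


class ContourError(ValueError):
    """Raised when a contour or contour stack is invalid."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Contour:
    """A closed planar polygon on an axial slice.

    Parameters
    ----------
    z_mm : float
        Axial position of the slice in mm.
    points : (N, 2) ndarray
        Ordered vertices (x, y) in mm.  The closing point is implicit
        and must not be duplicated.
    """

    z_mm: float
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ContourError("contour points must be an (N, 2) array")
        if len(self.points) < 3:
            raise ContourError("contour needs at least 3 points")
        if not np.all(np.isfinite(self.points)) or not math.isfinite(self.z_mm):
            raise ContourError("contour coordinates must be finite")
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        closing = np.linalg.norm(self.points[-1] - self.points[0])
        if np.any(d == 0.0):
            raise ContourError("contour has identical consecutive points")
        if closing == 0.0:
            raise ContourError("closing point must not be duplicated")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def edge_lengths(self) -> np.ndarray:
        """Lengths of all edges including the closing edge."""
        closed = np.vstack([self.points, self.points[:1]])
        return np.linalg.norm(np.diff(closed, axis=0), axis=1)

    def perimeter(self) -> float:
        return float(self.edge_lengths().sum())

    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise orientation."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(
            0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def is_ccw(self) -> bool:
        return self.signed_area() > 0

    def reversed(self) -> "Contour":
        return Contour(self.z_mm, self.points[::-1].copy())

    def is_simple(self) -> bool:
        """True if the polygon does not self-intersect."""
        from shapely.geometry import LinearRing

        ring = LinearRing(self.points)
        return bool(ring.is_simple and ring.is_valid)


@dataclass
class ContourStack:
    """Contours of a single-component object sorted ascending in z."""

    contours: list
    frame: str = "LPS"

    def __post_init__(self) -> None:
        z = np.array([c.z_mm for c in self.contours], dtype=float)
        if len(z) and np.any(np.diff(z) <= 0):
            raise ContourError("contour z positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self):
        return iter(self.contours)

    @property
    def z_mm(self) -> np.ndarray:
        return np.array([c.z_mm for c in self.contours])


@dataclass
class TriangleMesh:
    """Triangle surface mesh.

    vertices : (V, 3) float array, mm
    facets   : (F, 3) int array of vertex indices; counter-clockwise
               winding seen from outside (right-hand-rule normals point
               outward for a closed, correctly oriented surface).
    """

    vertices: np.ndarray
    facets: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.facets = np.asarray(self.facets, dtype=np.int64).reshape(-1, 3)
        if len(self.facets) and (
            self.facets.min() < 0 or self.facets.max() >= len(self.vertices)
        ):
            raise MeshError("facet references an invalid vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_facets(self) -> int:
        return len(self.facets)

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of facet corner coordinates."""
        return self.vertices[self.facets]

    def facet_normals(self) -> np.ndarray:
        """Unit normals by the right-hand rule on facet winding."""
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(norm > 0, n / norm, 0.0)
        return unit

    def facet_areas(self) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])


@dataclass
class CompensatorGrid:
    """Row x column thickness matrix of a proton range compensator.

    thickness_mm[r, c] is the material thickness along the beam axis at
    the cell whose centre sits at
    ``origin_mm + (c * col_spacing, r * row_spacing)`` in the
    compensator tray frame.
    """

    thickness_mm: np.ndarray
    pixel_spacing_mm: tuple  # (row, col)
    origin_mm: tuple = (0.0, 0.0)
    base_thickness_mm: float = 0.0

    def __post_init__(self) -> None:
        self.thickness_mm = np.asarray(self.thickness_mm, dtype=float)
        if self.thickness_mm.ndim != 2:
            raise ValueError("thickness must be a 2-D matrix")
        if np.any(self.thickness_mm < 0):
            raise ValueError("thickness must be nonnegative")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel spacing must be positive")
        if np.all(self.thickness_mm == 0):
            warnings.warn("empty compensator: all thickness values are zero")

    @property
    def n_rows(self) -> int:
        return self.thickness_mm.shape[0]

    @property
    def n_cols(self) -> int:
        return self.thickness_mm.shape[1]


@dataclass
class ConformityReport:
    """Per-slice largest Euclidean design-to-print distance and summary."""

    per_slice_mm: list  # list of (z_mm, distance_mm)
    mean_mm: float
    sd_mm: float  # population (N) standard deviation
    registered: bool = False
    registration: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_slice_mm": [[float(z), float(d)] for z, d in self.per_slice_mm],
            "mean_mm": float(self.mean_mm),
            "sd_mm": float(self.sd_mm),
            "sd_definition": "population (N)",
            "registered": bool(self.registered),
            "registration": self.registration,
        }


@dataclass
class MaterialReport:
    """Measured CT and material properties of a printed object."""

    hu_mean: float = None
    hu_sd: float = None
    mass_density_g_cm3: float = None
    relative_electron_density: float = None
    relative_stopping_power: float = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mass_density_g_cm3 is not None and self.mass_density_g_cm3 <= 0:
            raise ValueError("mass density must be positive")

    def to_dict(self) -> dict:
        out = {}
        for k in (
            "hu_mean",
            "hu_sd",
            "mass_density_g_cm3",
            "relative_electron_density",
            "relative_stopping_power",
        ):
            v = getattr(self, k)
            out[k] = None if v is None else float(v)
        out["notes"] = dict(self.notes)
        return out


# ---------------------------------------------------------------------------
# Contour operations
# ---------------------------------------------------------------------------


def resample_contour(c: Contour, max_spacing_mm: float) -> Contour:
    """Subdivide polygon edges until none is longer than ``max_spacing_mm``.

    Original vertices are always preserved: an edge of length L is split
    into ceil(L / max_spacing_mm) equal parts, so the perimeter is
    unchanged and the output spacing is strictly <= the target.
    """
    if max_spacing_mm <= 0:
        raise ValueError("max_spacing_mm must be positive")
    pts = c.points
    closed = np.vstack([pts, pts[:1]])
    out = []
    for a, b in zip(closed[:-1], closed[1:]):
        length = float(np.linalg.norm(b - a))
        n_sub = max(1, math.ceil(length / max_spacing_mm - 1e-12))
        # fractions [0, 1) keep a, drop b (b is the next edge's a)
        frac = np.arange(n_sub) / n_sub
        out.append(a + frac[:, None] * (b - a))
    return Contour(c.z_mm, np.vstack(out))


def _cyclic_align(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Cyclically shift ``other`` to minimise the summed squared distance
    to ``ref`` (both (N, 2), same N, same orientation)."""
    n = len(ref)
    best_shift, best_cost = 0, np.inf
    for s in range(n):
        rolled = np.roll(other, -s, axis=0)
        cost = float(np.sum((rolled - ref) ** 2))
        if cost < best_cost:
            best_cost, best_shift = cost, s
    return np.roll(other, -best_shift, axis=0)


def correspond_contours(a: Contour, b: Contour) -> tuple:
    """Bring two contours into vertex-wise correspondence.

    Both are resampled by arc length to N = max(point counts) vertices,
    normalised to counter-clockwise orientation, and ``b`` is cyclically
    aligned to ``a`` by minimising the sum of squared inter-vertex
    distances over cyclic shifts.
    """
    a = a if a.is_ccw() else a.reversed()
    b = b if b.is_ccw() else b.reversed()
    n = max(a.n_points, b.n_points)
    pa = _resample_to_count(a.points, n)
    pb = _resample_to_count(b.points, n)
    pb = _cyclic_align(pa, pb)
    return Contour(a.z_mm, pa), Contour(b.z_mm, pb)


def _resample_to_count(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to exactly n vertices by arc length,
    keeping vertex 0 fixed."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.arange(n) / n * total
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    out = np.column_stack([x, y])
    # numerical duplicates can arise when n >> original count; nudge them
    d = np.linalg.norm(np.diff(np.vstack([out, out[:1]]), axis=0), axis=1)
    if np.any(d == 0.0):
        keep = np.concatenate([[True], d[:-1] > 0.0])
        out = out[keep]
    return out


def interpolate_stack(
    s: ContourStack, target_spacing_mm: float = 1.0
) -> ContourStack:
    """Insert linearly blended contours so adjacent z-gaps are <= target.

    Each gap dz is split into ceil(dz / target) equal sub-gaps; the
    intermediate contours are vertex-wise linear blends of the bounding
    contours after correspondence (common point count, CCW orientation,
    cyclic alignment).  Original slice positions are preserved exactly.
    """
    if len(s) < 2:
        raise ContourError("need at least 2 contours to interpolate")
    if target_spacing_mm <= 0:
        raise ValueError("target_spacing_mm must be positive")
    out = []
    contours = list(s.contours)
    for lo, hi in zip(contours[:-1], contours[1:]):
        dz = hi.z_mm - lo.z_mm
        n_sub = max(1, math.ceil(dz / target_spacing_mm - 1e-12))
        a, b = correspond_contours(lo, hi)
        out.append(lo)
        for k in range(1, n_sub):
            f = k / n_sub
            pts = (1 - f) * a.points + f * b.points
            out.append(Contour(lo.z_mm + f * dz, pts))
    out.append(contours[-1])
    return ContourStack(out, frame=s.frame)


def contour_at(s: ContourStack, z_mm: float) -> Contour:
    """Linearly blended contour of the stack at an arbitrary z inside
    its range (exact slice returned verbatim)."""
    z = s.z_mm
    if z_mm < z[0] - 1e-9 or z_mm > z[-1] + 1e-9:
        raise ContourError(f"z={z_mm} outside stack range [{z[0]}, {z[-1]}]")
    idx = int(np.searchsorted(z, z_mm))
    if idx < len(z) and abs(z[idx] - z_mm) < 1e-9:
        return s.contours[idx]
    if idx > 0 and abs(z[idx - 1] - z_mm) < 1e-9:
        return s.contours[idx - 1]
    lo, hi = s.contours[idx - 1], s.contours[idx]
    a, b = correspond_contours(lo, hi)
    f = (z_mm - lo.z_mm) / (hi.z_mm - lo.z_mm)
    return Contour(z_mm, (1 - f) * a.points + f * b.points)


# ---------------------------------------------------------------------------
# Mesh operations
# ---------------------------------------------------------------------------


def _edge_table(facets: np.ndarray):
    """Directed and undirected edge arrays of a facet list."""
    e = np.concatenate(
        [facets[:, [0, 1]], facets[:, [1, 2]], facets[:, [2, 0]]]
    )
    und = np.sort(e, axis=1)
    return e, und


def validate_mesh(m: TriangleMesh) -> dict:
    """Report-only integrity check of a triangle mesh.

    Returns a dict with watertightness (every undirected edge shared by
    exactly two facets), orientation consistency (each undirected edge
    traversed once in each direction), connected components with their
    Euler characteristics, degenerate/duplicate facets, open edges and
    the signed volume (meaningful only when watertight).
    """
    report = {
        "n_vertices": m.n_vertices,
        "n_facets": m.n_facets,
        "watertight": False,
        "oriented": False,
        "outward": False,
        "open_edges": [],
        "degenerate_facets": [],
        "duplicate_facets": [],
        "components": [],
        "euler_characteristics": [],
        "signed_volume_mm3": None,
    }
    if m.n_facets == 0:
        return report

    directed, und = _edge_table(m.facets)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    open_edges = uniq[counts != 2]
    report["open_edges"] = [tuple(int(i) for i in e) for e in open_edges]
    report["watertight"] = len(open_edges) == 0

    # orientation: each undirected edge must appear once per direction
    d_uniq, d_counts = np.unique(directed, axis=0, return_counts=True)
    report["oriented"] = report["watertight"] and bool(np.all(d_counts == 1))

    areas = m.facet_areas()
    report["degenerate_facets"] = [int(i) for i in np.flatnonzero(areas <= 1e-12)]
    f_sorted = np.sort(m.facets, axis=1)
    _, inv, fc = np.unique(f_sorted, axis=0, return_inverse=True, return_counts=True)
    report["duplicate_facets"] = [int(i) for i in np.flatnonzero(fc[inv] > 1)]

    # connected components over the vertex graph induced by facets
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    rows = directed[:, 0]
    cols = directed[:, 1]
    g = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m.n_vertices,) * 2
    )
    n_comp, labels = connected_components(g, directed=False)
    used = np.unique(m.facets)
    comp_ids = np.unique(labels[used])
    report["components"] = int(len(comp_ids))
    for cid in comp_ids:
        verts = np.flatnonzero(labels == cid)
        fmask = np.isin(m.facets[:, 0], verts)
        v = len(verts)
        f = int(fmask.sum())
        sub_und = np.sort(
            np.concatenate(
                [
                    m.facets[fmask][:, [0, 1]],
                    m.facets[fmask][:, [1, 2]],
                    m.facets[fmask][:, [2, 0]],
                ]
            ),
            axis=1,
        )
        e = len(np.unique(sub_und, axis=0))
        report["euler_characteristics"].append(int(v - e + f))

    if report["watertight"] and report["oriented"]:
        vol = _signed_volume(m)
        report["signed_volume_mm3"] = float(vol)
        report["outward"] = vol > 0
    return report


def _signed_volume(m: TriangleMesh) -> float:
    t = m.triangles()
    return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)


def mesh_volume(m: TriangleMesh) -> float:
    """Enclosed volume in mm^3 via the divergence theorem.

    Requires a watertight, consistently oriented mesh; positive for
    outward orientation.
    """
    _, und = _edge_table(m.facets)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    bad = uniq[counts != 2]
    if len(bad):
        shown = ", ".join(str(tuple(int(i) for i in e)) for e in bad[:10])
        raise MeshError(
            f"mesh is not watertight: {len(bad)} open edge(s): {shown}"
        )
    return _signed_volume(m)


def scale_mesh(
    m: TriangleMesh,
    factors,
    fixed_point=None,
) -> TriangleMesh:
    """Scale a mesh anisotropically about a fixed point.

    The default fixed point is the minimum corner of the bounding box so
    a printed part's base stays put.  Volume scales by fx*fy*fz.
    """
    f = np.asarray(factors, dtype=float)
    if f.shape == ():
        f = np.repeat(f, 3)
    if f.shape != (3,) or np.any(f <= 0):
        raise ValueError("scale factors must be 3 positive numbers")
    if fixed_point is None:
        fixed_point = m.vertices.min(axis=0)
    fixed_point = np.asarray(fixed_point, dtype=float)
    verts = (m.vertices - fixed_point) * f + fixed_point
    return TriangleMesh(verts, m.facets.copy())
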