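"""Surface reconstruction: contour stacks and compensator grids to
watertight triangle meshes ready for STL export.

The lateral wall of a contour-stack solid is built from triangle strips
between corresponding vertices of adjacent slices (after resampling to
a common point count and cyclic alignment); the top and bottom openings
are capped with a constrained Delaunay triangulation of the end
contours, so every produced surface is closed, consistently oriented
outward and has Euler characteristic 2.

A note on "Delaunay" here: a 3-D Delaunay tetrahedralisation of the full
point cloud would return the convex hull, not the object surface, so the
Delaunay criterion is applied where it is well-posed — the planar caps
and the compensator top surface — while the walls follow the slice
correspondence.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import (
    CompensatorGrid,
    Contour,
    ContourError,
    ContourStack,
    MeshError,
    TriangleMesh,
    _resample_to_count,
    resample_contour,
    validate_mesh,
)

__all__ = [
    "triangulate_polygon",
    "stack_to_mesh",
    "grid_to_mesh",
    "mesh_to_printable",
]


# ---------------------------------------------------------------------------
# Constrained Delaunay triangulation of a simple polygon
# ---------------------------------------------------------------------------


def _cross2(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _incircle(pa, pb, pc, pd) -> float:
    """> 0 when pd lies strictly inside the circumcircle of the
    counter-clockwise triangle (pa, pb, pc)."""
    adx, ady = pa[0] - pd[0], pa[1] - pd[1]
    bdx, bdy = pb[0] - pd[0], pb[1] - pd[1]
    cdx, cdy = pc[0] - pd[0], pc[1] - pd[1]
    alift = adx * adx + ady * ady
    blift = bdx * bdx + bdy * bdy
    clift = cdx * cdx + cdy * cdy
    return (
        adx * (bdy * clift - cdy * blift)
        - ady * (bdx * clift - cdx * blift)
        + alift * (bdx * cdy - cdx * bdy)
    )


def _ear_clip(points: np.ndarray) -> list:
    """Triangulate a simple CCW polygon by ear clipping.

    Returns index triples into ``points``; all triangles counter-
    clockwise.  O(n^2) with vectorised containment tests.
    """
    n = len(points)
    idx = list(range(n))
    tris = []
    scale = float(np.ptp(points, axis=0).max())
    area_eps = 1e-12 * scale * scale
    start = 0
    while len(idx) > 3:
        m = len(idx)
        clipped = False
        for off in range(m):
            k = (start + off) % m
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % m]
            p0, p1, p2 = points[i0], points[i1], points[i2]
            c = _cross2(p0, p1, p2)
            if c <= area_eps:  # reflex or collinear vertex: not an ear
                continue
            others = np.array(
                [j for j in idx if j not in (i0, i1, i2)], dtype=int
            )
            q = points[others]
            # inside-or-on test (signed areas vs each ear edge)
            s0 = (p1[0] - p0[0]) * (q[:, 1] - p0[1]) - (p1[1] - p0[1]) * (
                q[:, 0] - p0[0]
            )
            s1 = (p2[0] - p1[0]) * (q[:, 1] - p1[1]) - (p2[1] - p1[1]) * (
                q[:, 0] - p1[0]
            )
            s2 = (p0[0] - p2[0]) * (q[:, 1] - p2[1]) - (p0[1] - p2[1]) * (
                q[:, 0] - p2[0]
            )
            if np.any((s0 >= -area_eps) & (s1 >= -area_eps) & (s2 >= -area_eps)):
                continue
            tris.append((i0, i1, i2))
            idx.pop(k)
            start = k % len(idx)
            clipped = True
            break
        if not clipped:
            # numerical fallback: clip the most convex vertex
            best_k, best_c = 0, -np.inf
            for k in range(m):
                i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % m]
                c = _cross2(points[i0], points[i1], points[i2])
                if c > best_c:
                    best_c, best_k = c, k
            k = best_k
            tris.append((idx[k - 1], idx[k], idx[(k + 1) % m]))
            idx.pop(k)
            start = k % len(idx)
    tris.append(tuple(idx))
    return tris


def _lawson_flip(points: np.ndarray, tris: list, constrained: set) -> list:
    """Flip interior edges of a triangulation until every non-constrained
    edge satisfies the (tolerance-guarded) empty-circumcircle criterion.

    Cocircular configurations are tie-broken by leaving them unflipped,
    which keeps the procedure deterministic and terminating.
    """
    scale = float(np.ptp(points, axis=0).max())
    tol = 1e-9 * scale**4

    tris = [list(t) for t in tris]
    alive = [True] * len(tris)

    def edges_of(t):
        return [
            tuple(sorted((t[0], t[1]))),
            tuple(sorted((t[1], t[2]))),
            tuple(sorted((t[2], t[0]))),
        ]

    edge2tris: dict = {}
    for ti, t in enumerate(tris):
        for e in edges_of(t):
            edge2tris.setdefault(e, set()).add(ti)

    stack = [e for e in edge2tris if e not in constrained]
    max_flips = 20 * len(points) ** 2 + 10000
    flips = 0
    while stack:
        e = stack.pop()
        if e in constrained:
            continue
        ts = [ti for ti in edge2tris.get(e, ()) if alive[ti]]
        if len(ts) != 2:
            continue
        t1i, t2i = ts
        a, b = e
        t1, t2 = tris[t1i], tris[t2i]
        # orient t1 as (a, b, c): find directed edge a->b in t1
        if (a, b) not in (
            (t1[0], t1[1]),
            (t1[1], t1[2]),
            (t1[2], t1[0]),
        ):
            a, b = b, a
            if (a, b) not in (
                (t1[0], t1[1]),
                (t1[1], t1[2]),
                (t1[2], t1[0]),
            ):
                continue  # inconsistent orientation; leave edge alone
        c = next(v for v in t1 if v not in (a, b))
        d = next(v for v in t2 if v not in (a, b))
        if _incircle(points[a], points[b], points[c], points[d]) <= tol:
            continue
        # flip shared edge (a, b) -> (c, d)
        new1, new2 = [a, d, c], [d, b, c]
        if (
            _cross2(points[a], points[d], points[c]) <= 0
            or _cross2(points[d], points[b], points[c]) <= 0
        ):
            continue  # quad not strictly convex; flipping would invert
        for ti in (t1i, t2i):
            alive[ti] = False
            for ee in edges_of(tris[ti]):
                edge2tris[ee].discard(ti)
        for nt in (new1, new2):
            ti = len(tris)
            tris.append(nt)
            alive.append(True)
            for ee in edges_of(nt):
                edge2tris.setdefault(ee, set()).add(ti)
        for ee in (
            tuple(sorted((a, d))),
            tuple(sorted((d, b))),
            tuple(sorted((b, c))),
            tuple(sorted((c, a))),
        ):
            if ee not in constrained:
                stack.append(ee)
        flips += 1
        if flips > max_flips:
            raise MeshError("Delaunay flipping did not terminate")
    return [tuple(t) for t, ok in zip(tris, alive) if ok]


def triangulate_polygon(points: np.ndarray) -> np.ndarray:
    """Constrained Delaunay triangulation of a simple polygon.

    ``points`` is an (N, 2) array of polygon vertices (closing point not
    duplicated) in counter-clockwise order.  The boundary edges are
    enforced as constraints; interior edges satisfy the empty-
    circumcircle criterion (Lawson flips after ear clipping).  Returns
    (T, 3) index triples, all counter-clockwise.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 3:
        raise ContourError("polygon needs at least 3 vertices")
    if n == 3:
        return np.array([[0, 1, 2]])
    constrained = {tuple(sorted((i, (i + 1) % n))) for i in range(n)}
    tris = _ear_clip(points)
    tris = _lawson_flip(points, tris, constrained)
    return np.array(tris, dtype=np.int64)


# ---------------------------------------------------------------------------
# Contour stack -> closed solid
# ---------------------------------------------------------------------------


def _aligned_rings(s: ContourStack, target_spacing_mm: float):
    """Resample every contour to a common point count, orient CCW and
    chain cyclic alignment down the stack; then densify in z so adjacent
    ring gaps are <= target_spacing_mm.

    Returns (z_list, rings) with rings an (n_rings, N, 2) array in
    vertex-wise correspondence.
    """
    from .geometry import _cyclic_align

    resampled = [resample_contour(c, target_spacing_mm) for c in s]
    n_common = max(c.n_points for c in resampled)
    rings = []
    zs = []
    prev = None
    for c in resampled:
        cc = c if c.is_ccw() else c.reversed()
        pts = _resample_to_count(cc.points, n_common)
        if len(pts) != n_common:
            raise ContourError("resampling failed to reach common point count")
        if prev is not None:
            pts = _cyclic_align(prev, pts)
        rings.append(pts)
        zs.append(c.z_mm)
        prev = pts

    dense_z, dense_rings = [zs[0]], [rings[0]]
    for (z0, r0), (z1, r1) in zip(zip(zs[:-1], rings[:-1]), zip(zs[1:], rings[1:])):
        dz = z1 - z0
        n_sub = max(1, math.ceil(dz / target_spacing_mm - 1e-12))
        for k in range(1, n_sub):
            f = k / n_sub
            dense_z.append(z0 + f * dz)
            dense_rings.append((1 - f) * r0 + f * r1)
        dense_z.append(z1)
        dense_rings.append(r1)
    return dense_z, np.asarray(dense_rings)


def stack_to_mesh(
    s: ContourStack, target_spacing_mm: float = 1.0
) -> TriangleMesh:
    """Convert a contour stack to a watertight solid mesh.

    Contours are resampled so no edge exceeds ``target_spacing_mm`` and
    intermediate slices are inserted so no z-gap exceeds it either;
    corresponding vertices of adjacent slices are joined by triangle
    strips and the two end contours are capped by constrained Delaunay
    triangulation.
    """
    if len(s) < 2:
        raise ContourError("need at least 2 slices to build a solid")
    for c in s:
        if not c.is_simple():
            raise ContourError(f"contour at z={c.z_mm} is self-intersecting")

    zs, rings = _aligned_rings(s, target_spacing_mm)
    n_rings, n_pts, _ = rings.shape

    vertices = np.concatenate(
        [
            np.column_stack([r, np.full(n_pts, z)])
            for z, r in zip(zs, rings)
        ]
    )

    facets = []
    for k in range(n_rings - 1):
        lo = k * n_pts
        hi = (k + 1) * n_pts
        i = np.arange(n_pts)
        j = (i + 1) % n_pts
        # outward winding for CCW rings viewed from +z
        facets.append(np.column_stack([lo + i, lo + j, hi + j]))
        facets.append(np.column_stack([lo + i, hi + j, hi + i]))
    facets = np.concatenate(facets)

    bottom = triangulate_polygon(rings[0])
    top = triangulate_polygon(rings[-1])
    # top cap CCW from +z is outward; bottom cap must face -z
    top_f = top + (n_rings - 1) * n_pts
    bottom_f = bottom[:, ::-1]
    mesh = TriangleMesh(vertices, np.concatenate([facets, top_f, bottom_f]))

    from .geometry import _signed_volume

    if _signed_volume(mesh) < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.facets[:, ::-1])
    return mesh


# ---------------------------------------------------------------------------
# Compensator grid -> closed solid
# ---------------------------------------------------------------------------


def grid_to_mesh(g: CompensatorGrid, beam_axis: str = "+z") -> TriangleMesh:
    """Extrude a compensator thickness grid into a watertight solid.

    The top surface is the bilinear height field split cell-by-cell
    along a fixed diagonal (a valid Delaunay triangulation of the
    rectangular grid positions, where the cocircular cell corners are
    tie-broken deterministically); vertical walls follow the grid
    perimeter down to a flat base at z = 0.  The enclosed volume equals
    the prismatoid integral (mean vertex height x projected area summed
    over top triangles) exactly.

    ``beam_axis='-z'`` mirrors the solid so material extends along -z
    (beam pointing down onto the tray); the default keeps thickness
    along +z.
    """
    if beam_axis not in ("+z", "-z"):
        raise ValueError("beam_axis must be '+z' or '-z'")
    R, C = g.n_rows, g.n_cols
    if R < 2 or C < 2:
        raise ValueError("grid footprint has zero area (need >= 2x2 cells)")
    sr, sc = g.pixel_spacing_mm
    ox, oy = g.origin_mm
    h = g.thickness_mm + g.base_thickness_mm

    xs = ox + np.arange(C) * sc
    ys = oy + np.arange(R) * sr
    X, Y = np.meshgrid(xs, ys)  # [row, col]

    top = np.column_stack([X.ravel(), Y.ravel(), h.ravel()])

    def tid(r, c):
        return r * C + c

    facets = []
    r, c = np.meshgrid(np.arange(R - 1), np.arange(C - 1), indexing="ij")
    r, c = r.ravel(), c.ravel()
    # grid is row-major with y increasing along rows: (c+1, r) is +x,
    # (c, r+1) is +y; CCW in the xy-plane means normal +z (upward/outward)
    facets.append(np.column_stack([tid(r, c), tid(r, c + 1), tid(r + 1, c + 1)]))
    facets.append(np.column_stack([tid(r, c), tid(r + 1, c + 1), tid(r + 1, c)]))

    # perimeter ring, CCW viewed from +z: bottom row left->right, right
    # column up, top row right->left, left column down
    ring = (
        [tid(0, c) for c in range(C)]
        + [tid(r, C - 1) for r in range(1, R)]
        + [tid(R - 1, c) for c in range(C - 2, -1, -1)]
        + [tid(r, 0) for r in range(R - 2, 0, -1)]
    )
    ring = np.array(ring)
    n_ring = len(ring)
    base_start = len(top)
    base = np.column_stack(
        [top[ring][:, 0], top[ring][:, 1], np.zeros(n_ring)]
    )
    vertices = np.vstack([top, base])

    i = np.arange(n_ring)
    j = (i + 1) % n_ring
    walls = [
        np.column_stack([ring[j], ring[i], base_start + i]),
        np.column_stack([ring[j], base_start + i, base_start + j]),
    ]

    base_tris = triangulate_polygon(base[:, :2])
    base_f = base_start + base_tris[:, ::-1]  # face -z

    mesh = TriangleMesh(
        vertices, np.concatenate(facets + walls + [base_f])
    )
    if beam_axis == "-z":
        v = mesh.vertices.copy()
        v[:, 2] *= -1.0
        mesh = TriangleMesh(v, mesh.facets[:, ::-1])
    return mesh


# ---------------------------------------------------------------------------
# Print preparation
# ---------------------------------------------------------------------------


def mesh_to_printable(
    m: TriangleMesh,
    output_path,
    scale_factors=None,
    ascii: bool = False,
    allow_open: bool = False,
) -> dict:
    """Validate, optionally scale, and write a mesh to STL.

    Refuses to write a non-watertight or inconsistently oriented mesh
    unless ``allow_open`` is set; returns the final validation report.
    """
    from .formats import write_stl
    from .geometry import scale_mesh

    report = validate_mesh(m)
    if not (report["watertight"] and report["oriented"] and report["outward"]):
        if not allow_open:
            open_edges = report["open_edges"][:10]
            raise MeshError(
                "refusing to write a mesh that failed validation "
                f"(watertight={report['watertight']}, "
                f"oriented={report['oriented']}, outward={report['outward']}, "
                f"open edges: {open_edges}); pass allow_open=True to override"
            )
    if scale_factors is not None:
        m = scale_mesh(m, scale_factors)
        report = validate_mesh(m)
    write_stl(m, output_path, mode="ascii" if ascii else "binary")
    return report
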