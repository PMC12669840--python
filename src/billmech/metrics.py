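"""Univariate bill descriptors: arc length, arc:chord curvature, outer
surface area, tip sharpness ratio, and included angle.

Conventions: the specimen is aligned with its chord (tip -> proximal culmen
end) along +x and the tip at the origin.  "Distal millimeters" are slabs
along the aligned x axis; triangles straddling slab planes are clipped
exactly (polygon splitting), since the distal slab spans few triangles and
vertex binning would bias the areas.  The included angle is measured on the
dorsal (x-y) silhouette: twice the arctangent of the silhouette half-width at
0.5 mm from the tip over 0.5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmarks import ContourCurve
from .synthetic import BillSpecimen


@dataclass
class BillMetrics:
    arc_length: float
    chord_length: float
    arc_chord_ratio: float
    outer_surface_area: float
    area_distal_mm: float      # A1: outer area of the distal-most 1 mm
    area_second_mm: float      # A2: outer area of the second-most distal 1 mm
    sharpness_ratio: float     # 1 - A1/A2; larger = sharper
    included_angle: float      # degrees; smaller = sharper


def arc_chord(culmen: ContourCurve | np.ndarray) -> tuple[float, float, float]:
    """(arc length, chord length, arc:chord ratio) of the culmen polyline."""
    pts = culmen.points if isinstance(culmen, ContourCurve) else np.asarray(culmen, float)
    if len(pts) < 2:
        raise ValueError("need at least 2 culmen points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = float(seg.sum())
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord <= 1e-9 * max(arc, 1e-300):
        raise ValueError("zero chord: endpoints coincide")
    return arc, chord, arc / chord


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, float)
    f = np.asarray(faces, int)
    return 0.5 * np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
    )


def outer_surface_area(mesh, face_indices: np.ndarray | None = None) -> float:
    """Sum of triangle areas over a face selection (mm^2)."""
    faces = mesh.faces if face_indices is None else mesh.faces[np.asarray(face_indices, int)]
    if len(faces) == 0:
        raise ValueError("empty face selection")
    return float(triangle_areas(mesh.vertices, faces).sum())


def _clip_polygon_halfspace(poly: np.ndarray, x0: float, keep_below: bool) -> np.ndarray:
    """Sutherland-Hodgman clip of a 3D polygon by the plane x = x0."""
    out = []
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        fa, fb = a[0] - x0, b[0] - x0
        ina = fa <= 0 if keep_below else fa >= 0
        inb = fb <= 0 if keep_below else fb >= 0
        if ina:
            out.append(a)
        if ina != inb:
            t = fa / (fa - fb)
            out.append(a + t * (b - a))
    return np.array(out) if out else np.empty((0, 3))


def _polygon_area(poly: np.ndarray) -> float:
    """Area of a planar convex 3D polygon (fan decomposition)."""
    if len(poly) < 3:
        return 0.0
    v = poly - poly[0]
    return float(0.5 * np.linalg.norm(np.cross(v[1:-1], v[2:]), axis=1).sum())


def slab_surface_area(vertices: np.ndarray, faces: np.ndarray, x0: float, x1: float) -> float:
    """Total triangle area inside the slab x in [x0, x1), with exact clipping."""
    v = np.asarray(vertices, float)
    f = np.asarray(faces, int)
    tx = v[f, 0]
    cand = (tx.min(axis=1) < x1) & (tx.max(axis=1) > x0)
    total = 0.0
    for tri in f[cand]:
        poly = v[tri]
        poly = _clip_polygon_halfspace(poly, x0, keep_below=False)
        if len(poly) >= 3:
            poly = _clip_polygon_halfspace(poly, x1, keep_below=True)
        if len(poly) >= 3:
            total += _polygon_area(poly)
    return total


def sharpness_ratio(
    mesh, tip: np.ndarray, face_indices: np.ndarray | None = None
) -> tuple[float, float, float]:
    """(A1, A2, 1 - A1/A2): outer areas of the two distal millimeters.

    The mesh must be aligned (longitudinal axis = +x, extending distal to
    proximal from the stored tip point); slabs are measured from the tip's x.
    """
    tipx = float(np.asarray(tip, float)[0])
    faces = mesh.faces if face_indices is None else mesh.faces[np.asarray(face_indices, int)]
    a1 = slab_surface_area(mesh.vertices, faces, tipx, tipx + 1.0)
    a2 = slab_surface_area(mesh.vertices, faces, tipx + 1.0, tipx + 2.0)
    if a2 <= 0:
        raise ValueError("second distal millimeter has zero area; bill too short?")
    return a1, a2, 1.0 - a1 / a2


def included_angle(mesh, tip: np.ndarray, distance: float = 0.5) -> float:
    """Bill-tip included angle (degrees) from the dorsal-view silhouette.

    The silhouette half-width is taken at ``distance`` mm from the tip along
    +x (from the cross-section of the mesh with that plane); the angle is that
    of the isoceles triangle with apex at the tip and base 2*half_width.
    """
    v = np.asarray(mesh.vertices, float)
    f = np.asarray(mesh.faces, int)
    x_cut = float(np.asarray(tip, float)[0]) + distance
    edges = np.unique(np.sort(f[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1), axis=0)
    xa, xb = v[edges[:, 0], 0], v[edges[:, 1], 0]
    crossing = (np.minimum(xa, xb) <= x_cut) & (np.maximum(xa, xb) >= x_cut) & (xa != xb)
    if not np.any(crossing):
        return 0.0
    a, b = v[edges[crossing, 0]], v[edges[crossing, 1]]
    t = (x_cut - a[:, 0]) / (b[:, 0] - a[:, 0])
    ys = a[:, 1] + t * (b[:, 1] - a[:, 1])
    half_width = 0.5 * float(ys.max() - ys.min())
    if half_width <= 0:
        import warnings

        warnings.warn("degenerate silhouette: zero width at the cut plane")
        return 0.0
    return float(np.degrees(2.0 * np.arctan2(half_width, distance)))


def compute_metrics(specimen: BillSpecimen) -> BillMetrics:
    """All descriptors for one (aligned) specimen with surface mesh+contours."""
    arc, chord, ratio = arc_chord(specimen.contours["culmen"])
    dorsal = specimen.face_regions.get("dorsal")
    sa = outer_surface_area(specimen.surface_mesh, dorsal)
    tip = specimen.meta.get("tip_point", specimen.contours["culmen"].points[0])
    # sharpness uses the full outer (non-base) surface of the distal slabs
    outer = None
    if specimen.face_regions:
        outer = np.concatenate([idx for lbl, idx in specimen.face_regions.items()
                                if lbl != "base"])
    a1, a2, sharp = sharpness_ratio(specimen.surface_mesh, tip, outer)
    angle = included_angle(specimen.surface_mesh, tip)
    return BillMetrics(
        arc_length=arc, chord_length=chord, arc_chord_ratio=ratio,
        outer_surface_area=sa, area_distal_mm=a1, area_second_mm=a2,
        sharpness_ratio=sharp, included_angle=angle,
    )


def metrics_table(specimens: list[BillSpecimen]) -> pd.DataFrame:
    """One row per specimen, one column per metric."""
    rows = []
    for sp in specimens:
        m = compute_metrics(sp)
        rows.append({"specimen_id": sp.id, "sex": sp.sex, **m.__dict__})
    return pd.DataFrame(rows).set_index("specimen_id")
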