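"""Parametric synthetic bill geometries and dimorphic populations.

Real study material (museum skins digitized by photogrammetry, two CT scans)
is emulated by a parametric family: the culmen (dorsal midline of the upper
bill) is a planar circular arc — the unique planar curve realizing a given
arc:chord ratio — and a bilaterally symmetric cross-section (half-ellipse
dorsal vault over a shallow ventral face, so the tomia are distinct lateral
edges) is swept along it, shrinking toward the tip as a power law of arc-length
position.  A thin keratin shell (rhamphotheca) of constant thickness wraps a
stiffer bone core; the two-region tetrahedral volume mesh shares interface
nodes, i.e. the tissues are bonded.

Geometry conventions: lengths in mm; tip at the origin; the chord from tip to
the proximal culmen end lies along +x; the sagittal plane is x-z with the
dorsal direction toward +z and the bird's left at +y.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .landmarks import ContourCurve
from .tetmesh import REGION_CORE, REGION_SHELL, TetMesh, split_prisms

DORSAL_FRACTION = 0.85  # share of base_height above the tomium plane


@dataclass(frozen=True)
class BillParams:
    """Ground-truth shape parameters of one synthetic bill.

    arc_length
        Length of the culmen arc, tip to proximal culmen end (mm).
    arc_chord_ratio
        Culmen arc length over chord length; 1 is a straight bill.
    base_height, base_width
        Cross-section extents at the bill base (mm).
    taper_exponent
        Cross-section scale varies as ((u + t0)/(L + t0))**taper_exponent
        with u the arc-length distance from the tip; larger exponents give
        finer, sharper tips.
    shell_thickness
        Rhamphotheca (keratin shell) thickness (mm).
    tip_truncation
        Small positive length t0 keeping the swept sections non-degenerate at
        the apex (the apex itself is closed with a cone fan).
    """

    arc_length: float = 40.0
    arc_chord_ratio: float = 1.05
    base_height: float = 3.0
    base_width: float = 4.0
    taper_exponent: float = 1.0
    shell_thickness: float = 0.15
    tip_truncation: float = 0.05

    def validate(self) -> "BillParams":
        if self.arc_chord_ratio < 1.0:
            raise ValueError("arc_chord_ratio must be >= 1 (no real arc otherwise)")
        for name in ("arc_length", "base_height", "base_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.taper_exponent <= 0:
            raise ValueError("taper_exponent must be positive")
        if self.tip_truncation < 0:
            raise ValueError("tip_truncation must be >= 0")
        if not 0 < self.shell_thickness < min(self.base_height, self.base_width) / 2:
            raise ValueError("shell_thickness must be in (0, min(height, width)/2)")
        return self


@dataclass
class PopulationSpec:
    """Specification of a two-sex synthetic population with known truth."""

    n_per_group: int
    group_means: dict[str, BillParams]
    noise_sd: dict[str, float] = field(default_factory=dict)
    landmark_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 specimens per group")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd entries must be >= 0")


@dataclass
class BillSpecimen:
    """One individual: surface mesh, labeled contours, optional volume mesh."""

    id: str
    sex: str
    surface_mesh: "object" = None           # trimesh.Trimesh
    face_regions: dict[str, np.ndarray] = field(default_factory=dict)
    contours: dict[str, ContourCurve] = field(default_factory=dict)
    volume_mesh: TetMesh | None = None
    truth: BillParams | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# centerline (culmen arc)

def arc_angle_from_ratio(ratio: float) -> float:
    """Subtended angle theta of a circular arc with given arc:chord ratio.

    Inverts ratio = theta / (2 sin(theta/2)) on (0, 2*pi); ratio 1 gives the
    straight-line limit theta = 0.
    """
    if ratio < 1.0:
        raise ValueError("arc:chord ratio must be >= 1")
    if ratio == 1.0 or ratio - 1.0 < 1e-12:
        return 0.0
    f = lambda t: t / (2.0 * np.sin(t / 2.0)) - ratio
    return float(brentq(f, 1e-9, 2.0 * np.pi - 1e-9, xtol=1e-14, rtol=1e-15))


class BillGeometry:
    """Analytic parametric map of a synthetic bill.

    The culmen is the unit-speed arc P(u), u in [0, L] from tip to base, lying
    in the x-z plane with its chord on the x axis and the bulge toward +z.
    Cross-sections hang below the culmen in the plane spanned by y and the
    in-plane normal n(u).
    """

    def __init__(self, params: BillParams):
        self.params = params.validate()
        L = params.arc_length
        self.L = L
        self.theta = arc_angle_from_ratio(params.arc_chord_ratio)
        if self.theta > 0:
            self.R = L / self.theta
            self.chord = 2.0 * self.R * np.sin(self.theta / 2.0)
            # arc center below the chord midpoint
            self.center = np.array([self.chord / 2.0, 0.0, -self.R * np.cos(self.theta / 2.0)])
        else:
            self.R = np.inf
            self.chord = L
            self.center = None

    # -- curve frame ---------------------------------------------------

    def point(self, u):
        u = np.asarray(u, dtype=float)
        if self.theta == 0.0:
            return np.stack([u, np.zeros_like(u), np.zeros_like(u)], axis=-1)
        psi = -self.theta / 2.0 + self.theta * u / self.L
        return self.center + self.R * np.stack(
            [np.sin(psi), np.zeros_like(psi), np.cos(psi)], axis=-1
        )

    def tangent(self, u):
        """Unit tangent pointing from tip toward base."""
        u = np.asarray(u, dtype=float)
        if self.theta == 0.0:
            t = np.zeros(u.shape + (3,))
            t[..., 0] = 1.0
            return t
        psi = -self.theta / 2.0 + self.theta * u / self.L
        return np.stack([np.cos(psi), np.zeros_like(psi), -np.sin(psi)], axis=-1)

    def normal(self, u):
        """Unit dorsal normal (away from the arc center, +z when straight)."""
        u = np.asarray(u, dtype=float)
        if self.theta == 0.0:
            n = np.zeros(u.shape + (3,))
            n[..., 2] = 1.0
            return n
        psi = -self.theta / 2.0 + self.theta * u / self.L
        return np.stack([np.sin(psi), np.zeros_like(psi), np.cos(psi)], axis=-1)

    # -- cross-section -------------------------------------------------

    def scale(self, u):
        p = self.params
        return ((np.asarray(u, dtype=float) + p.tip_truncation)
                / (self.L + p.tip_truncation)) ** p.taper_exponent

    def half_width(self, u):
        return 0.5 * self.params.base_width * self.scale(u)

    def dorsal_height(self, u):
        return DORSAL_FRACTION * self.params.base_height * self.scale(u)

    def ventral_depth(self, u):
        return (1.0 - DORSAL_FRACTION) * self.params.base_height * self.scale(u)

    def section_boundary_2d(self, u: float, m_dorsal: int, m_ventral: int) -> np.ndarray:
        """Closed cross-section boundary at station u in local (a, b) coords.

        ``a`` is lateral (+ = bird's left, maps to +y), ``b`` vertical with the
        culmen at b = 0 and the section hanging below.  Ring order: left
        tomium -> dorsal vault -> right tomium -> ventral face back to start
        (counterclockwise).  ``m_dorsal`` must be even and ``m_ventral`` odd
        so midline points exist and the ring is exactly mirror-symmetric.
        """
        w, hd, dv = self.half_width(u), self.dorsal_height(u), self.ventral_depth(u)
        alpha = np.linspace(0.0, np.pi, m_dorsal + 1)
        dorsal = np.column_stack([w * np.cos(alpha), hd * (np.sin(alpha) - 1.0)])
        a_v = np.linspace(-w, w, m_ventral + 2)[1:-1]
        ventral = np.column_stack([a_v, -hd - dv * (1.0 - (a_v / w) ** 2)])
        return np.vstack([dorsal, ventral])

    def section_to_3d(self, u: float, ab: np.ndarray) -> np.ndarray:
        P = self.point(u)
        n = self.normal(u)
        ab = np.asarray(ab, dtype=float)
        return P + ab[:, :1] * np.array([0.0, 1.0, 0.0]) + ab[:, 1:2] * n

    def dorsal_surface_point(self, u, alpha):
        """Parametric map of the dorsal (outer maxillary) surface patch."""
        u = np.asarray(u, dtype=float)
        alpha = np.asarray(alpha, dtype=float)
        w, hd = self.half_width(u), self.dorsal_height(u)
        a = w * np.cos(alpha)
        b = hd * (np.sin(alpha) - 1.0)
        P = self.point(u)
        n = self.normal(u)
        out = P + np.asarray(a)[..., None] * np.array([0.0, 1.0, 0.0]) + np.asarray(b)[..., None] * n
        return out


def _station_positions(L: float, n_u: int, grading: float) -> np.ndarray:
    """Arc-length stations, clustered toward the tip for grading > 1."""
    return L * (np.arange(1, n_u + 1) / n_u) ** grading


def ring_mirror_map(m_dorsal: int, m_ventral: int) -> np.ndarray:
    """Ring index permutation realizing the sagittal reflection a -> -a."""
    dorsal = np.arange(m_dorsal, -1, -1)
    ventral = m_dorsal + np.arange(m_ventral, 0, -1)
    return np.concatenate([dorsal, ventral])


def generate_centerline(params: BillParams, n: int = 200) -> np.ndarray:
    """Sample the culmen arc as an (n, 3) polyline from tip to base."""
    geo = BillGeometry(params)
    u = np.linspace(0.0, geo.L, n)
    return geo.point(u)


def generate_contours(
    params: BillParams, n_u: int = 80, grading: float = 1.5
) -> dict[str, ContourCurve]:
    """Analytic contour polylines (culmen + tomia) without building a mesh.

    Point-for-point identical to the contours emitted by
    :func:`generate_surface` at the same resolution.
    """
    geo = BillGeometry(params)
    u = np.concatenate([[0.0], _station_positions(geo.L, n_u, grading)])
    apex = geo.point(0.0)
    culmen = np.vstack([apex, geo.point(u[1:])])
    yhat = np.array([0.0, 1.0, 0.0])
    n_vec = geo.normal(u[1:])
    base_pts = geo.point(u[1:]) - geo.dorsal_height(u[1:])[:, None] * n_vec
    w = geo.half_width(u[1:])[:, None]
    left = np.vstack([apex, base_pts + w * yhat])
    right = np.vstack([apex, base_pts - w * yhat])
    return {
        "culmen": ContourCurve("culmen", culmen),
        "left_tomium": ContourCurve("left_tomium", left),
        "right_tomium": ContourCurve("right_tomium", right),
    }


def generate_surface(
    params: BillParams,
    n_u: int = 80,
    m_dorsal: int = 16,
    m_ventral: int = 7,
    grading: float = 1.5,
    id: str = "synthetic",
    sex: str = "F",
) -> BillSpecimen:
    """Build a watertight triangulated bill surface with labeled contours.

    Face regions: ``dorsal`` (outer maxillary surface between the tomia,
    including the dorsal part of the apex fan), ``ventral``, ``tip`` (apex
    fan) and ``base`` (proximal cap).
    """
    import trimesh

    params = params.validate()
    if m_dorsal % 2 or m_ventral % 2 == 0:
        raise ValueError("m_dorsal must be even and m_ventral odd (mirror symmetry)")
    geo = BillGeometry(params)
    u = _station_positions(geo.L, n_u, grading)
    m = m_dorsal + 1 + m_ventral

    verts = [geo.point(0.0)[None, :]]  # apex = vertex 0
    for ui in u:
        ab = geo.section_boundary_2d(ui, m_dorsal, m_ventral)
        verts.append(geo.section_to_3d(ui, ab))
    base_center = geo.section_to_3d(
        u[-1], np.array([[0.0, -(geo.dorsal_height(u[-1]) + geo.ventral_depth(u[-1])) / 2]])
    )
    verts.append(base_center)
    V = np.vstack(verts)

    def rid(i: int, j: int) -> int:  # station i (1-based), ring position j
        return 1 + (i - 1) * m + (j % m)

    faces, labels = [], []
    # apex fan
    for j in range(m):
        faces.append([0, rid(1, j + 1), rid(1, j)])
        labels.append("dorsal" if j < m_dorsal else "ventral")
    # lateral quads
    for i in range(1, n_u):
        for j in range(m):
            a, b = rid(i, j), rid(i, j + 1)
            c, d = rid(i + 1, j + 1), rid(i + 1, j)
            faces.append([a, b, c])
            faces.append([a, c, d])
            lbl = "dorsal" if j < m_dorsal else "ventral"
            labels.extend([lbl, lbl])
    # base cap
    cid = len(V) - 1
    for j in range(m):
        faces.append([cid, rid(n_u, j), rid(n_u, j + 1)])
        labels.append("base")

    F = np.array(faces)
    signed_vol = np.einsum("ij,ij->i", V[F[:, 0]], np.cross(V[F[:, 1]], V[F[:, 2]])).sum() / 6.0
    if signed_vol < 0:
        F = F[:, [0, 2, 1]]
    mesh = trimesh.Trimesh(vertices=V, faces=F, process=False)

    labels = np.array(labels)
    regions = {lbl: np.where(labels == lbl)[0] for lbl in ("dorsal", "ventral", "base")}

    # contours straight from the parametric map (exactly on mesh vertices)
    apex = V[0]
    cul_idx = [0] + [rid(i, m_dorsal // 2) for i in range(1, n_u + 1)]
    lt_idx = [0] + [rid(i, 0) for i in range(1, n_u + 1)]
    rt_idx = [0] + [rid(i, m_dorsal) for i in range(1, n_u + 1)]
    contours = {
        "culmen": ContourCurve("culmen", V[cul_idx]),
        "left_tomium": ContourCurve("left_tomium", V[lt_idx]),
        "right_tomium": ContourCurve("right_tomium", V[rt_idx]),
    }
    meta = {
        "tip_point": apex.copy(),
        "tip_tangent": geo.tangent(0.0),
        "chord_length": geo.chord,
        "mesh_resolution": {"n_u": n_u, "m_dorsal": m_dorsal, "m_ventral": m_ventral,
                            "grading": grading},
    }
    return BillSpecimen(id=id, sex=sex, surface_mesh=mesh, face_regions=regions,
                        contours=contours, truth=params, meta=meta)


# ---------------------------------------------------------------------------
# volume meshing

def _inward_offsets(ring: np.ndarray, t: float, safety: float = 0.45) -> np.ndarray:
    """Offset a closed CCW 2D ring inward by up to t per vertex.

    The inward normal at a vertex is the normalized bisector of its edge
    normals; the offset distance is clamped by a ray-cast to the opposite
    boundary so thin sections degrade to all-shell instead of inverting.
    """
    n = len(ring)
    nxt = np.roll(ring, -1, axis=0)
    prv = np.roll(ring, 1, axis=0)
    e1 = ring - prv
    e2 = nxt - ring
    # inward normal of a CCW ring is the +90 degree rotation of the tangent
    def inward(e):
        t_ = e / np.linalg.norm(e, axis=1, keepdims=True)
        return np.column_stack([-t_[:, 1], t_[:, 0]])
    n1, n2 = inward(e1), inward(e2)
    ni = n1 + n2
    norms = np.linalg.norm(ni, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    ni /= norms
    # mitre factor: along the bisector, clearance t from both edges needs t/cos(phi/2)
    mitre = np.maximum(np.einsum("ij,ij->i", ni, n1), 0.2)

    # ray-cast each inward normal against all edges to bound the offset
    dist = np.full(n, np.inf)
    a = ring
    b = nxt
    for i in range(n):
        o, d = ring[i], ni[i]
        # segment a + s*(b-a), ray o + r*d
        ab = b - a
        denom = ab[:, 0] * (-d[1]) - ab[:, 1] * (-d[0])
        ok = np.abs(denom) > 1e-14
        ao = o - a
        s = np.where(ok, (ao[:, 0] * (-d[1]) - ao[:, 1] * (-d[0])) / np.where(ok, denom, 1.0), -1)
        r = np.where(ok, (ab[:, 0] * ao[:, 1] - ab[:, 1] * ao[:, 0]) / np.where(ok, denom, 1.0), -1)
        hit = ok & (s >= 0) & (s <= 1) & (r > 1e-9)
        if np.any(hit):
            dist[i] = r[hit].min()
    off = np.minimum(t / mitre, safety * dist)
    return ring + ni * off[:, None]


def generate_volume(
    specimen: BillSpecimen,
    shell_thickness: float | None = None,
    n_u: int = 24,
    m_dorsal: int = 12,
    m_ventral: int = 5,
    n_radial: int = 2,
    grading: float = 1.3,
) -> BillSpecimen:
    """Attach a two-region (shell/core) tetrahedral volume mesh.

    Cross-sections along the culmen arc are meshed with a boundary ring, an
    inward-offset ring at the shell-core interface (node-shared, i.e. bonded),
    and radial core layers collapsing to a center node; consecutive sections
    are joined by prisms split into face-compatible tetrahedra, and the tip is
    closed with a cone fan to the apex.
    """
    if specimen.truth is None:
        raise ValueError("volume meshing requires a parametric specimen (truth set)")
    params = specimen.truth
    if shell_thickness is not None:
        params = replace(params, shell_thickness=shell_thickness)
    params.validate()
    if m_dorsal % 2 or m_ventral % 2 == 0:
        raise ValueError("m_dorsal must be even and m_ventral odd")
    geo = BillGeometry(params)
    t = params.shell_thickness
    u = _station_positions(geo.L, n_u, grading)
    m = m_dorsal + 1 + m_ventral
    n_sec = m * 2 + m * (n_radial - 1) + 1  # boundary + offset + inner rings + center

    # 2D section template connectivity (same for every station)
    tris2d: list[list[int]] = []
    lab2d: list[int] = []

    def ring_ids(r: int) -> np.ndarray:
        return np.arange(r * m, (r + 1) * m)

    n_rings = n_radial + 1  # boundary, offset, inner ...
    for r in range(n_rings - 1):
        cur, nxt = ring_ids(r), ring_ids(r + 1)
        for j in range(m):
            a, b = cur[j], cur[(j + 1) % m]
            c, d = nxt[(j + 1) % m], nxt[j]
            tris2d.append([a, b, c])
            tris2d.append([a, c, d])
            lab = REGION_SHELL if r == 0 else REGION_CORE
            lab2d.extend([lab, lab])
    center2d = n_sec - 1
    last = ring_ids(n_rings - 1)
    for j in range(m):
        tris2d.append([last[j], last[(j + 1) % m], center2d])
        lab2d.append(REGION_CORE)
    tris2d = np.array(tris2d)
    lab2d = np.array(lab2d)

    # nodes: apex then one block per station
    pts = [geo.point(0.0)[None, :]]
    for ui in u:
        boundary = geo.section_boundary_2d(ui, m_dorsal, m_ventral)
        offset = _inward_offsets(boundary, t)
        center = np.array([0.0, -(geo.dorsal_height(ui) + geo.ventral_depth(ui)) / 2.0])
        rings = [boundary, offset]
        for r in range(2, n_rings):
            frac = (r - 1) / (n_rings - 1)
            rings.append(offset * (1 - frac) + center[None, :] * frac)
        ab = np.vstack(rings + [center[None, :]])
        pts.append(geo.section_to_3d(ui, ab))
    points = np.vstack(pts)

    def sec_node(i: int, local: np.ndarray) -> np.ndarray:
        return 1 + i * n_sec + local

    tets, region = [], []
    # apex cone: section-0 triangles connected to apex node 0
    tri0 = sec_node(0, tris2d)
    apex_tets = np.column_stack([np.zeros(len(tri0), dtype=np.int64),
                                 tri0[:, 0], tri0[:, 1], tri0[:, 2]])
    tets.append(apex_tets)
    region.append(lab2d.copy())
    # prisms between consecutive stations
    for i in range(n_u - 1):
        bot = sec_node(i, tris2d)
        top = sec_node(i + 1, tris2d)
        prisms = np.hstack([bot, top])
        tets.append(split_prisms(prisms))
        region.append(np.repeat(lab2d, 3))
    mesh = TetMesh(
        points=points,
        tets=np.vstack(tets),
        region=np.concatenate(region),
        node_sets={
            "apex": np.array([0]),
            "base": sec_node(n_u - 1, np.arange(n_sec)),
        },
    ).orient()
    specimen.volume_mesh = mesh
    specimen.meta["volume_resolution"] = {
        "n_u": n_u, "m_dorsal": m_dorsal, "m_ventral": m_ventral,
        "n_radial": n_radial, "grading": grading,
    }
    return specimen


# ---------------------------------------------------------------------------
# populations

_NOISE_FIELDS = ("arc_length", "arc_chord_ratio", "base_height", "base_width",
                 "taper_exponent", "shell_thickness", "tip_truncation")

#: Study conditions: a dimorphic population mirroring the field pattern in
#: large hermits — males with straighter (lower arc:chord), longer,
#: sharper-tipped, slightly larger bills.  Taper exponents sit below 0.75 so
#: the distal shaft stays stout enough that bending energy is governed by the
#: whole arch rather than diverging at the sharp apex (real bills are stout
#: keratin+bone shafts whose sharpness is a localized tip feature).
FEMALE_MEAN = BillParams(arc_length=38.0, arc_chord_ratio=1.12, base_height=3.0,
                         base_width=4.0, taper_exponent=0.45)
MALE_MEAN = BillParams(arc_length=42.0, arc_chord_ratio=1.01, base_height=3.3,
                       base_width=4.4, taper_exponent=0.6)
DEFAULT_NOISE_SD = {
    "arc_length": 1.2,
    "arc_chord_ratio": 0.02,
    "base_height": 0.09,
    "base_width": 0.12,
    "taper_exponent": 0.04,
}


def default_population_spec(seed: int = 0, n_per_group: int = 8,
                            null: bool = False) -> PopulationSpec:
    """The default dimorphic study population (or its null-hypothesis twin).

    ``null=True`` gives both sexes the female mean: sex labels carry no shape
    signal, which is the generator used for type-I error calibration.
    """
    means = {"F": FEMALE_MEAN, "M": FEMALE_MEAN if null else MALE_MEAN}
    return PopulationSpec(
        n_per_group=n_per_group,
        group_means=means,
        noise_sd=dict(DEFAULT_NOISE_SD),
        landmark_jitter_sd=0.05,
        seed=seed,
    )


def draw_params(mean: BillParams, noise_sd: dict[str, float], rng: np.random.Generator,
                max_retries: int = 100) -> BillParams:
    """One parameter draw: Gaussian noise around the group mean, redrawn
    (up to ``max_retries``) until the parameter set is geometrically valid."""
    for _ in range(max_retries):
        kw = asdict(mean)
        for name in _NOISE_FIELDS:
            sd = noise_sd.get(name, 0.0)
            if sd > 0:
                kw[name] = kw[name] + sd * rng.standard_normal()
        try:
            return BillParams(**kw).validate()
        except ValueError:
            continue
    raise RuntimeError(f"no valid parameter draw after {max_retries} retries")


def sample_population(
    spec: PopulationSpec,
    contours_only: bool = False,
    n_u: int = 80,
    **surface_kwargs,
) -> list[BillSpecimen]:
    """Draw a population of synthetic specimens.

    Deterministic given ``spec.seed``; each specimen uses an independent
    substream keyed by (seed, counter), so enlarging the population does not
    perturb earlier draws.  ``contours_only=True`` skips surface meshing (fast
    path for statistical calibration; contour coordinates are identical).
    Landmark jitter is isotropic Gaussian noise added to contour points after
    generation, emulating digitization error; it never touches the mesh.
    """
    specimens = []
    counter = 0
    for sex in sorted(spec.group_means):
        mean = spec.group_means[sex]
        for i in range(spec.n_per_group):
            rng = np.random.default_rng([spec.seed, counter])
            counter += 1
            params = draw_params(mean, spec.noise_sd, rng)
            sid = f"{sex}{i + 1:02d}"
            if contours_only:
                sp = BillSpecimen(id=sid, sex=sex, truth=params,
                                  contours=generate_contours(params, n_u=n_u))
                geo = BillGeometry(params)
                sp.meta = {"tip_point": geo.point(0.0), "tip_tangent": geo.tangent(0.0),
                           "chord_length": geo.chord}
            else:
                sp = generate_surface(params, n_u=n_u, id=sid, sex=sex, **surface_kwargs)
            if spec.landmark_jitter_sd > 0:
                for lbl, c in sp.contours.items():
                    noisy = c.points + spec.landmark_jitter_sd * rng.standard_normal(c.points.shape)
                    sp.contours[lbl] = ContourCurve(lbl, noisy)
            specimens.append(sp)
    return specimens


# ---------------------------------------------------------------------------
# I/O

def export_specimen(specimen: BillSpecimen, outdir: str | Path) -> None:
    """Write meshes (STL + PLY, VTK volume), contours CSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = specimen.id
    if specimen.surface_mesh is not None:
        specimen.surface_mesh.export(outdir / f"{sid}_surface.stl")
        specimen.surface_mesh.export(outdir / f"{sid}_surface.ply", encoding="ascii")
    if specimen.volume_mesh is not None:
        specimen.volume_mesh.write_vtk(outdir / f"{sid}_volume.vtk")
    if specimen.contours:
        with open(outdir / f"{sid}_contours.csv", "w") as fh:
            fh.write("specimen_id,curve_label,point_index,x,y,z\n")
            for lbl, c in specimen.contours.items():
                for i, (x, y, z) in enumerate(c.points):
                    fh.write(f"{sid},{lbl},{i},{x:.9g},{y:.9g},{z:.9g}\n")
    if specimen.truth is not None:
        with open(outdir / f"{sid}_truth.json", "w") as fh:
            json.dump({"id": sid, "sex": specimen.sex, "params": asdict(specimen.truth)},
                      fh, indent=2)
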