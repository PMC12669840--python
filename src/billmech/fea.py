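"""Linear-static finite elements on labeled tetrahedral meshes.

Isotropic linear elasticity with 10-node (quadratic) tetrahedra by default
and a 4-node option for fast checks.  Midside nodes sit exactly at edge
midpoints, so the geometric map is affine and the Jacobian is constant per
element.  Units: mm / MPa / N, so forces in N, displacements in mm, stresses
in MPa and energies in mJ (N*mm).

Stabbing boundary conditions follow the comparative protocol: all degrees of
freedom fixed on the proximal cut plane (attachment to the head), and the
total force shared over the nodes of the distal millimeter of the tip, either
along the chord ("horizontal" stabbing, +x) or along the bill-tip axis
("parallel" stabbing, the centerline tangent at the tip pointing proximally).

Buckling resistance uses the linearized eigenvalue problem
(K + lambda * K_g(u0)) phi = 0 with K_g the stress (geometric) stiffness
assembled from the static pre-solution; the smallest positive lambda is the
buckling load factor (multiplier on the applied load at predicted buckling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .tetmesh import REGION_CORE, REGION_SHELL, TetMesh

@dataclass(frozen=True)
class MaterialSpec:
    young_modulus: float  # MPa
    poisson_ratio: float

    def __post_init__(self):
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson's ratio must be in [0, 0.5)")


#: Bill tissue properties: keratin rhamphotheca shell over a bone core,
#: Poisson's ratio 0.4 for both.
DEFAULT_MATERIALS = {
    REGION_SHELL: MaterialSpec(1700.0, 0.4),
    REGION_CORE: MaterialSpec(7300.0, 0.4),
}


@dataclass
class BoundaryConditions:
    fixed_nodes: np.ndarray
    load_nodes: np.ndarray
    total_force: np.ndarray  # N
    load_mode: str = "horizontal"
    load_weights: np.ndarray | None = None  # per-node shares, sum 1

    def __post_init__(self):
        self.fixed_nodes = np.unique(np.asarray(self.fixed_nodes, dtype=int))
        self.load_nodes = np.unique(np.asarray(self.load_nodes, dtype=int))
        self.total_force = np.asarray(self.total_force, dtype=float)
        if len(self.fixed_nodes) == 0 or len(self.load_nodes) == 0:
            raise ValueError("fixed and load node sets must be non-empty")
        if np.intersect1d(self.fixed_nodes, self.load_nodes).size:
            raise ValueError("fixed and load node sets must be disjoint")
        if np.linalg.norm(self.total_force) <= 0:
            raise ValueError("total force must be non-zero")


@dataclass
class FESolution:
    displacements: np.ndarray      # (n_nodes, 3) mm
    element_vm_stress: np.ndarray  # MPa, at element centroids
    element_volumes: np.ndarray    # mm^3
    strain_energy: float           # mJ
    f_external: np.ndarray = field(repr=False, default=None)


@dataclass
class PerformanceSummary:
    peak_vm_98: float
    mwam_vm: float
    strain_energy: float
    buckling_load_factor: float | None = None


# ---------------------------------------------------------------------------
# element technology

_GRAD_L = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
_EDGES10 = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
_GA = 0.5854101966249685
_GB = 0.1381966011250105
_GAUSS4 = np.array(
    [[_GA, _GB, _GB, _GB], [_GB, _GA, _GB, _GB], [_GB, _GB, _GA, _GB], [_GB, _GB, _GB, _GA]]
)  # barycentric coordinates; weights 1/4 each


def _shape_gradients(lam: np.ndarray, order: int) -> np.ndarray:
    """Reference-space gradients dN/d(xi) at barycentric point lam.

    Returns (n_nodes_per_elem, 3).
    """
    if order == 1:
        return _GRAD_L.copy()
    g = np.zeros((10, 3))
    for i in range(4):
        g[i] = (4.0 * lam[i] - 1.0) * _GRAD_L[i]
    for e, (a, b) in enumerate(_EDGES10):
        g[4 + e] = 4.0 * (lam[a] * _GRAD_L[b] + lam[b] * _GRAD_L[a])
    return g


class FEModel:
    """A ready-to-assemble FE model: nodes, elements, per-element material."""

    def __init__(self, mesh: TetMesh, materials: dict[int, MaterialSpec] | None = None,
                 order: int = 2):
        if order not in (1, 2):
            raise ValueError("order must be 1 (TET4) or 2 (TET10)")
        materials = materials or DEFAULT_MATERIALS
        vols = mesh.volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise ValueError(f"inverted element {bad} (volume {vols[bad]:.3g})")
        for lbl in np.unique(mesh.region):
            if lbl not in materials:
                raise ValueError(f"no material for region label {lbl}")
        self.mesh = mesh
        self.order = order
        if order == 2:
            self.points, self.elems = mesh.quadratic_nodes()
        else:
            self.points, self.elems = mesh.points, mesh.tets
        self.region = mesh.region
        self.E = np.array([materials[r].young_modulus for r in mesh.region])
        self.nu = np.array([materials[r].poisson_ratio for r in mesh.region])
        self.materials = materials
        self._grads = None  # cache: (n_elem, n_gauss, npe, 3) physical gradients
        self._detJ = None

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_dof(self) -> int:
        return 3 * self.n_nodes

    def node_set(self, name: str) -> np.ndarray:
        """Lift a corner-node set to the FE node set (adds midside nodes whose
        edge endpoints both belong to the set)."""
        base = np.asarray(self.mesh.node_sets[name], dtype=int)
        if self.order == 1:
            return base
        mask = np.zeros(self.mesh.n_points, dtype=bool)
        mask[base] = True
        edges = self.mesh.tets[:, [[0, 1], [1, 2], [2, 0], [0, 3], [1, 3], [2, 3]]].reshape(-1, 2)
        uniq = np.unique(np.sort(edges, axis=1), axis=0)
        mid_in = mask[uniq[:, 0]] & mask[uniq[:, 1]]
        return np.concatenate([base, self.mesh.n_points + np.where(mid_in)[0]])

    # -- gradients -------------------------------------------------------

    def _physical_gradients(self):
        if self._grads is not None:
            return self._grads, self._detJ
        p = self.mesh.points[self.mesh.tets]
        J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=2)
        detJ = np.linalg.det(J)
        Jinv = np.linalg.inv(J)
        if self.order == 1:
            gref = _shape_gradients(None, 1)[None, :, :]  # 1 "gauss" point
        else:
            gref = np.stack([_shape_gradients(lam, 2) for lam in _GAUSS4])
        # physical gradient: dN/dx = Jinv^T @ dN/dxi
        grads = np.einsum("eji,gnj->egni", Jinv, gref)
        self._grads, self._detJ = grads, detJ
        return grads, detJ

    def centroid_gradients(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical shape-function gradients at element centroids."""
        p = self.mesh.points[self.mesh.tets]
        J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=2)
        detJ = np.linalg.det(J)
        Jinv = np.linalg.inv(J)
        lam = np.full(4, 0.25)
        gref = _shape_gradients(lam, self.order if self.order == 2 else 1)
        grads = np.einsum("eji,nj->eni", Jinv, gref)
        return grads, detJ


def assemble(model: FEModel) -> sp.csr_matrix:
    """Global stiffness matrix (symmetric positive semidefinite)."""
    grads, detJ = model._physical_gradients()
    n_g = grads.shape[1]
    w = detJ / 6.0 / n_g  # equal Gauss weights summing to the element volume
    lam = model.E * model.nu / ((1 + model.nu) * (1 - 2 * model.nu))
    mu = model.E / (2 * (1 + model.nu))

    # K[i a, j b] = lam g_ia g_jb + mu (g_ib g_ja + delta_ab g_i . g_j)
    npe = grads.shape[2]
    Ke = np.zeros((len(detJ), npe, 3, npe, 3))
    eye = np.eye(3)
    for g in range(n_g):
        G = grads[:, g]  # (E, npe, 3)
        Ke += np.einsum("e,eia,ejb->eiajb", lam * w, G, G)
        Ke += np.einsum("e,eib,eja->eiajb", mu * w, G, G)
        Ke += np.einsum("e,eij,ab->eiajb", mu * w, np.einsum("eic,ejc->eij", G, G), eye)

    dof = (3 * model.elems[:, :, None] + np.arange(3)[None, None, :]).reshape(len(detJ), -1)
    rows = np.repeat(dof, 3 * npe, axis=1).ravel()
    cols = np.tile(dof, (1, 3 * npe)).ravel()
    K = sp.coo_matrix(
        (Ke.reshape(len(detJ), -1).ravel(), (rows, cols)),
        shape=(model.n_dof, model.n_dof),
    ).tocsr()
    return K


def _force_vector(model: FEModel, bc: BoundaryConditions) -> np.ndarray:
    f = np.zeros(model.n_dof)
    w = bc.load_weights
    if w is None:
        w = np.full(len(bc.load_nodes), 1.0 / len(bc.load_nodes))
    for node, wi in zip(bc.load_nodes, w):
        f[3 * node: 3 * node + 3] += wi * bc.total_force
    return f


def _reduce(K: sp.csr_matrix, fixed: np.ndarray, n_dof: int):
    fixed_dof = (3 * fixed[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(n_dof), fixed_dof)
    return K[free][:, free].tocsc(), free


def solve_static(model: FEModel, K: sp.csr_matrix, bc: BoundaryConditions,
                 lu=None) -> FESolution:
    """Solve K u = f with the fixed set clamped; recover centroid stresses.

    Pass a prefactorized ``lu`` (from :func:`factorize`) to reuse across load
    cases on the same model.
    """
    f = _force_vector(model, bc)
    Kff, free = _reduce(K, bc.fixed_nodes, model.n_dof)
    if lu is None:
        lu = spla.splu(Kff)
    try:
        u_f = lu.solve(f[free])
    except RuntimeError as err:  # pragma: no cover - singular systems
        raise RuntimeError(f"singular system (under-constrained?): {err}") from None
    if not np.all(np.isfinite(u_f)):
        raise RuntimeError("singular system: non-finite displacements")
    u = np.zeros(model.n_dof)
    u[free] = u_f
    disp = u.reshape(-1, 3)

    vm, vols, _ = element_stresses(model, disp)
    energy = 0.5 * float(u @ f)
    return FESolution(displacements=disp, element_vm_stress=vm,
                      element_volumes=vols, strain_energy=energy, f_external=f)


def factorize(model: FEModel, K: sp.csr_matrix, fixed_nodes: np.ndarray):
    """LU-factorize the reduced stiffness for reuse over several load cases."""
    Kff, free = _reduce(K, np.unique(np.asarray(fixed_nodes, int)), model.n_dof)
    return spla.splu(Kff), free


def element_stresses(model: FEModel, disp: np.ndarray):
    """Centroid stress per element: (von Mises, volumes, full tensor (E,6))."""
    grads, detJ = model.centroid_gradients()
    ue = disp[model.elems]  # (E, npe, 3)
    gradu = np.einsum("enk,ena->eka", ue, grads)  # du_k/dx_a
    eps = 0.5 * (gradu + gradu.transpose(0, 2, 1))
    lam = model.E * model.nu / ((1 + model.nu) * (1 - 2 * model.nu))
    mu = model.E / (2 * (1 + model.nu))
    tr = np.trace(eps, axis1=1, axis2=2)
    sig = lam[:, None, None] * tr[:, None, None] * np.eye(3) + 2 * mu[:, None, None] * eps
    s = sig - np.trace(sig, axis1=1, axis2=2)[:, None, None] / 3.0 * np.eye(3)
    vm = np.sqrt(1.5 * np.einsum("eij,eij->e", s, s))
    voigt = np.stack([sig[:, 0, 0], sig[:, 1, 1], sig[:, 2, 2],
                      sig[:, 0, 1], sig[:, 1, 2], sig[:, 0, 2]], axis=1)
    return vm, detJ / 6.0, voigt


def vm_summaries(solution: FESolution) -> tuple[float, float]:
    """(peak, MWAM) of the element von Mises field.

    Peak is the 98th percentile over (unweighted) element values with linear
    order-statistic interpolation, excluding the top 2% as likely numerical
    singularities; MWAM is the element-volume-weighted arithmetic mean.
    """
    vm = solution.element_vm_stress
    if len(vm) == 0:
        raise ValueError("no elements")
    peak = float(np.percentile(vm, 98.0))
    mwam = float((vm * solution.element_volumes).sum() / solution.element_volumes.sum())
    return peak, mwam


def assemble_geometric(model: FEModel, disp: np.ndarray) -> sp.csr_matrix:
    """Stress (geometric) stiffness K_g from a static displacement state.

    K_g[i a, j b] = delta_ab * integral( grad N_i . sigma . grad N_j ), with
    the centroid stress tensor taken constant over each element.
    """
    _, _, voigt = element_stresses(model, disp)
    sig = np.empty((len(voigt), 3, 3))
    sig[:, 0, 0], sig[:, 1, 1], sig[:, 2, 2] = voigt[:, 0], voigt[:, 1], voigt[:, 2]
    sig[:, 0, 1] = sig[:, 1, 0] = voigt[:, 3]
    sig[:, 1, 2] = sig[:, 2, 1] = voigt[:, 4]
    sig[:, 0, 2] = sig[:, 2, 0] = voigt[:, 5]

    grads, detJ = model._physical_gradients()
    n_g = grads.shape[1]
    w = detJ / 6.0 / n_g
    npe = grads.shape[2]
    S = np.zeros((len(detJ), npe, npe))
    for g in range(n_g):
        G = grads[:, g]
        S += np.einsum("e,eia,eab,ejb->eij", w, G, sig, G)
    Kg = np.einsum("eij,ab->eiajb", S, np.eye(3))
    dof = (3 * model.elems[:, :, None] + np.arange(3)[None, None, :]).reshape(len(detJ), -1)
    rows = np.repeat(dof, 3 * npe, axis=1).ravel()
    cols = np.tile(dof, (1, 3 * npe)).ravel()
    return sp.coo_matrix(
        (Kg.reshape(len(detJ), -1).ravel(), (rows, cols)),
        shape=(model.n_dof, model.n_dof),
    ).tocsr()


def buckling_load_factor(
    model: FEModel,
    K: sp.csr_matrix,
    bc: BoundaryConditions,
    solution: FESolution | None = None,
    k_eigs: int = 4,
    cap: float = 1e8,
    lu=None,
) -> float | None:
    """Smallest positive eigenvalue of (K + lambda K_g) phi = 0.

    The factor multiplies the applied load: lambda * F is the predicted
    critical load.  Returns None when no positive eigenvalue exists below
    ``cap`` (no compressive instability under this load direction).
    """
    if solution is None:
        solution = solve_static(model, K, bc, lu=lu)
    Kg = assemble_geometric(model, solution.displacements)
    Kff, free = _reduce(K, bc.fixed_nodes, model.n_dof)
    Kgff, _ = _reduce(Kg, bc.fixed_nodes, model.n_dof)
    if lu is None:
        lu = spla.splu(Kff)
    n = Kff.shape[0]
    Minv = spla.LinearOperator((n, n), matvec=lu.solve)
    # Solve -K_g x = nu K x; positive nu give lambda = 1/nu.
    try:
        vals = spla.eigsh(
            (-Kgff).tocsc(), k=min(k_eigs, n - 1), M=Kff, Minv=Minv,
            which="LA", return_eigenvectors=False, maxiter=5000,
        )
    except spla.ArpackNoConvergence as err:
        vals = err.eigenvalues
        if vals is None or len(vals) == 0:
            raise RuntimeError("buckling eigensolve did not converge") from None
    nu_max = float(np.max(vals))
    if nu_max <= 1.0 / cap:
        return None
    return 1.0 / nu_max


def make_bc(
    model: FEModel,
    load_mode: str,
    total_force_mN: float,
    tip_point: np.ndarray | None = None,
    tip_tangent: np.ndarray | None = None,
    tip_extent: float = 1.0,
    base_set: str = "base",
    weighting: str = "equal",
) -> BoundaryConditions:
    """Stabbing boundary conditions on an aligned bill model.

    The mesh must be aligned with the tip at minimum x and the base at
    maximum x.  Fixed nodes come from the mesh's ``base`` node set (the
    proximal cut plane); load nodes are all FE nodes within ``tip_extent`` mm
    of the tip along x.  ``horizontal`` loads point along +x (the chord);
    ``parallel`` loads point along the bill-tip axis (centerline tangent at
    the tip, proximally).  Force input in mN, converted to N.
    """
    if load_mode not in ("horizontal", "parallel"):
        raise ValueError("load_mode must be 'horizontal' or 'parallel'")
    if total_force_mN <= 0:
        raise ValueError("total force must be positive")
    pts = model.points
    if tip_point is None:
        tip_point = pts[np.argmin(pts[:, 0])]
    tipx = float(np.asarray(tip_point, float)[0])
    fixed = model.node_set(base_set)
    load = np.where(pts[:, 0] <= tipx + tip_extent)[0]
    load = np.setdiff1d(load, fixed)
    if load.size == 0:
        raise ValueError("no load nodes within the distal tip extent")
    if load_mode == "horizontal" or tip_tangent is None:
        direction = np.array([1.0, 0.0, 0.0])
    else:
        direction = np.asarray(tip_tangent, dtype=float)
        direction = direction / np.linalg.norm(direction)
    force_N = direction * (total_force_mN / 1000.0)
    weights = None
    if weighting == "area":
        # share per corner node ~ 1/3 of adjacent boundary-face areas inside
        # the load region (midside nodes carry no share under this option)
        faces = model.mesh.boundary_faces()
        in_load = np.isin(faces, load).all(axis=1)
        faces = faces[in_load]
        if len(faces) == 0:
            raise ValueError("area weighting: no boundary faces fully inside the tip")
        p = model.mesh.points
        areas = 0.5 * np.linalg.norm(
            np.cross(p[faces[:, 1]] - p[faces[:, 0]], p[faces[:, 2]] - p[faces[:, 0]]),
            axis=1)
        acc = np.zeros(model.n_nodes)
        np.add.at(acc, faces.ravel(), np.repeat(areas / 3.0, 3))
        load = np.unique(faces)
        weights = acc[load] / acc[load].sum()
    elif weighting != "equal":
        raise ValueError("weighting must be 'equal' or 'area'")
    return BoundaryConditions(fixed_nodes=fixed, load_nodes=load,
                              total_force=force_N, load_mode=load_mode,
                              load_weights=weights)


def export_solution_vtk(model: FEModel, solution: FESolution, path) -> None:
    """Write the linear mesh with displacement vectors and element stresses."""
    from .tetmesh import write_vtk

    disp = solution.displacements[: model.mesh.n_points]
    write_vtk(path, model.mesh.points, model.mesh.tets,
              cell_data={"region": model.mesh.region,
                         "von_mises": solution.element_vm_stress},
              point_data={"displacement": disp})


def analyze(
    model: FEModel,
    bc: BoundaryConditions,
    K: sp.csr_matrix | None = None,
    with_buckling: bool = True,
    lu=None,
) -> tuple[FESolution, PerformanceSummary]:
    """Full single-model run: static solve, stress summaries, buckling."""
    if K is None:
        K = assemble(model)
    sol = solve_static(model, K, bc, lu=lu)
    peak, mwam = vm_summaries(sol)
    blf = buckling_load_factor(model, K, bc, solution=sol, lu=lu) if with_buckling else None
    return sol, PerformanceSummary(peak_vm_98=peak, mwam_vm=mwam,
                                   strain_energy=sol.strain_energy,
                                   buckling_load_factor=blf)
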