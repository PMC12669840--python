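"""Lightweight tetrahedral meshes: containers, prism/hex splitting, VTK export.

Volume meshes are built structurally (swept cross-sections for bills, hex
grids for validation beams/columns) and split into tetrahedra with
face-compatible templates, so no external mesh generator is required.
Region labels are integer cell data (1 = shell/rhamphotheca, 2 = bone core);
the shell-core interface shares nodes, which realizes bonded contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

REGION_SHELL = 1
REGION_CORE = 2

# Prism rotations bringing vertex i to position 0 with consistent orientation
# (bottom triangle 0-1-2, top 3-4-5 with 3 above 0).
_PRISM_ROT = np.array(
    [
        [0, 1, 2, 3, 4, 5],
        [1, 2, 0, 4, 5, 3],
        [2, 0, 1, 5, 3, 4],
        [3, 5, 4, 0, 2, 1],
        [4, 3, 5, 1, 0, 2],
        [5, 4, 3, 2, 1, 0],
    ]
)


@dataclass
class TetMesh:
    """Linear (4-node) tetrahedral mesh with integer region labels.

    ``node_sets`` carries named node index sets (e.g. ``base`` for the
    proximal cut plane, ``tip`` for the apex).  Quadratic (10-node) elements
    are derived on demand via :meth:`quadratic_nodes`.
    """

    points: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.region = np.asarray(self.region, dtype=np.int64)
        if self.tets.shape[1] != 4:
            raise ValueError("tets must be (m, 4)")
        if len(self.region) != len(self.tets):
            raise ValueError("region labels must match element count")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        """Signed tet volumes (positive for correctly oriented elements)."""
        p = self.points[self.tets]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def orient(self) -> "TetMesh":
        """Flip inverted elements so all volumes are positive (in place)."""
        v = self.volumes()
        bad = v < 0
        if np.any(bad):
            self.tets[bad] = self.tets[bad][:, [0, 2, 1, 3]]
        if np.any(np.isclose(self.volumes(), 0.0)):
            idx = np.where(np.isclose(self.volumes(), 0.0))[0]
            raise ValueError(f"degenerate (zero-volume) tetrahedra: {idx[:10].tolist()}")
        return self

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def region_volume(self, label: int) -> float:
        return float(self.volumes()[self.region == label].sum())

    def quadratic_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (all_points, tet10 connectivity) for 10-node elements.

        Midside nodes are created once per unique edge, so adjacent elements
        share them.  Node order per element: 4 corners then midpoints of
        edges (0-1, 1-2, 2-0, 0-3, 1-3, 2-3).
        """
        edges = self.tets[:, [[0, 1], [1, 2], [2, 0], [0, 3], [1, 3], [2, 3]]]
        flat = edges.reshape(-1, 2)
        flat_sorted = np.sort(flat, axis=1)
        uniq, inv = np.unique(flat_sorted, axis=0, return_inverse=True)
        mids = 0.5 * (self.points[uniq[:, 0]] + self.points[uniq[:, 1]])
        all_points = np.vstack([self.points, mids])
        mid_ids = self.n_points + inv.reshape(self.n_tets, 6)
        tet10 = np.hstack([self.tets, mid_ids])
        return all_points, tet10

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces that belong to exactly one tet (outer surface)."""
        f = self.tets[:, [[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]]].reshape(-1, 3)
        key = np.sort(f, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return f[counts[inv] == 1]

    def write_vtk(self, path: str | Path, cell_data: dict[str, np.ndarray] | None = None,
                  point_data: dict[str, np.ndarray] | None = None) -> None:
        write_vtk(path, self.points, self.tets,
                  cell_data={"region": self.region, **(cell_data or {})},
                  point_data=point_data)


def split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split triangular prisms into 3 tets each with face-compatible diagonals.

    ``prisms`` is (m, 6): bottom triangle then top triangle (vertex i+3 above
    vertex i).  Quad-face diagonals always emanate from the smallest global
    node id, so decompositions of prisms sharing a quad face agree.
    """
    prisms = np.asarray(prisms, dtype=np.int64)
    out = np.empty((len(prisms), 3, 4), dtype=np.int64)
    argmin = np.argmin(prisms, axis=1)
    rotated = np.take_along_axis(prisms, _PRISM_ROT[argmin], axis=1)
    v = rotated
    use_15 = np.minimum(v[:, 1], v[:, 5]) < np.minimum(v[:, 2], v[:, 4])
    # diagonal 1-5 on face 1-2-5-4
    a = use_15
    out[a, 0] = v[a][:, [0, 1, 2, 5]]
    out[a, 1] = v[a][:, [0, 1, 5, 4]]
    out[a, 2] = v[a][:, [0, 4, 5, 3]]
    b = ~use_15
    out[b, 0] = v[b][:, [0, 1, 2, 4]]
    out[b, 1] = v[b][:, [0, 4, 2, 5]]
    out[b, 2] = v[b][:, [0, 4, 5, 3]]
    return out.reshape(-1, 4)


def box_mesh(
    lx: float, ly: float, lz: float, nx: int, ny: int, nz: int,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TetMesh:
    """Structured tet mesh of a box, 6 tets per hex cell (Kuhn split).

    Node sets ``xmin``/``xmax`` mark the two end faces.  Used for FE
    validation against beam/column closed forms.
    """
    xs = np.linspace(0, lx, nx + 1) + origin[0]
    ys = np.linspace(0, ly, ny + 1) + origin[1]
    zs = np.linspace(0, lz, nz + 1) + origin[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    c = [nid(I + di, J + dj, K + dk)
         for di, dj, dk in [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                            (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]]
    # Kuhn triangulation: 6 tets around the main diagonal c0 - c7.
    paths = [(1, 3), (1, 5), (2, 3), (2, 6), (4, 5), (4, 6)]
    tets = np.concatenate(
        [np.column_stack([c[0], c[a], c[b], c[7]]) for a, b in paths]
    )
    mesh = TetMesh(
        points=pts,
        tets=tets,
        region=np.full(len(tets), REGION_CORE),
        node_sets={
            "xmin": np.where(np.isclose(pts[:, 0], origin[0]))[0],
            "xmax": np.where(np.isclose(pts[:, 0], origin[0] + lx))[0],
        },
    )
    return mesh.orient()


def write_vtk(
    path: str | Path,
    points: np.ndarray,
    tets: np.ndarray,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a tet mesh as legacy ASCII VTK (unstructured grid)."""
    points = np.asarray(points, dtype=float)
    tets = np.asarray(tets, dtype=np.int64)
    npe = tets.shape[1]
    if npe not in (4, 10):
        raise ValueError("only 4- or 10-node tets supported")
    vtk_type = 10 if npe == 4 else 24
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbillmech mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        np.savetxt(fh, points, fmt="%.9g")
        fh.write(f"CELLS {len(tets)} {len(tets) * (npe + 1)}\n")
        np.savetxt(fh, np.hstack([np.full((len(tets), 1), npe), tets]), fmt="%d")
        fh.write(f"CELL_TYPES {len(tets)}\n")
        np.savetxt(fh, np.full(len(tets), vtk_type), fmt="%d")
        if cell_data:
            fh.write(f"CELL_DATA {len(tets)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                if arr.dtype.kind in "iu":
                    fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%d")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.9g")
        if point_data:
            fh.write(f"POINT_DATA {len(points)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.9g")
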