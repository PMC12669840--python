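"""Generalized Procrustes analysis with sliding semilandmarks, bilateral
symmetry decomposition, and principal components of shape.

Superimposition removes position (centering), size (unit centroid size) and
orientation (proper orthogonal rotation to the consensus); semilandmarks then
slide along their tangent directions to minimize the Procrustes distance to
the consensus, are re-projected onto their source polyline, and the
superimposition is repeated until the consensus stabilizes.  Because bills
are bilaterally symmetric objects, shape analysis uses the symmetric
component: the average of each configuration with its mirrored-and-relabeled
copy after superimposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances to the centroid (mm)."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("centroid size needs at least 2 points")
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def _center_scale(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    s = np.sqrt((c ** 2).sum())
    if s < 1e-300:
        raise ValueError("configuration has zero centroid size (all points coincide)")
    return c / s


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det = +1) minimizing ||source @ R - target||."""
    M = source.T @ target
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


@dataclass
class ProcrustesFit:
    """GPA result: aligned shape coordinates and sizes.

    ``aligned`` has each configuration centered at the origin with unit
    centroid size; ``consensus`` is their coordinatewise mean.
    """

    aligned: np.ndarray           # (n, k, 3)
    consensus: np.ndarray         # (k, 3)
    centroid_sizes: np.ndarray    # (n,)
    n_slide_iterations: int
    converged: bool
    specimen_ids: list[str] | None = None
    ss_history: list[float] | None = None  # summed squared residuals per outer round


@dataclass
class SymmetryDecomposition:
    symmetric: np.ndarray   # (n, k, 3)
    asymmetric: np.ndarray  # (n, k, 3)


@dataclass
class ShapeSpace:
    scores: np.ndarray        # (n, n_pc)
    eigenvalues: np.ndarray   # variances along PCs
    pct_variance: np.ndarray  # sums to 100 over retained (nonzero) PCs
    loadings: np.ndarray      # (n_pc, 3k), orthonormal rows
    mean: np.ndarray          # (3k,)


def _tangents(config: LandmarkConfiguration, coords: np.ndarray) -> dict[int, np.ndarray]:
    """Unit tangent per semilandmark from central differences of neighbors."""
    out: dict[int, np.ndarray] = {}
    for i in config.semiland_idx:
        lbl_prev_next = config.curve_membership.get(int(i))
        if lbl_prev_next is None:
            continue
        _, prv, nxt = lbl_prev_next
        t = coords[nxt] - coords[prv]
        nrm = np.linalg.norm(t)
        if nrm < 1e-14:
            continue  # degenerate tangent: point treated as fixed this round
        out[int(i)] = t / nrm
    return out


def slide_semilandmarks(
    config: LandmarkConfiguration,
    coords: np.ndarray,
    consensus: np.ndarray,
    reproject: bool = True,
) -> np.ndarray:
    """Slide semilandmarks along their tangents toward the consensus.

    Each semilandmark moves along its tangent line by the projection of its
    residual onto the tangent (the Procrustes-distance-minimizing scalar),
    capped at the local inter-neighbor spacing to prevent curve fold-over.
    If ``reproject``, the slid point is snapped back onto the pre-slide
    polyline of its curve so points stay on the digitized contour.
    """
    coords = np.asarray(coords, dtype=float).copy()
    pre = coords.copy()
    tangents = _tangents(config, pre)
    for i, t in tangents.items():
        _, prv, nxt = config.curve_membership[int(i)]
        resid = consensus[i] - pre[i]
        step = float(resid @ t)
        cap = 0.5 * min(np.linalg.norm(pre[i] - pre[prv]), np.linalg.norm(pre[nxt] - pre[i]))
        step = float(np.clip(step, -cap, cap))
        coords[i] = pre[i] + step * t
    if reproject:
        for lbl, idx in config.curve_points.items():
            poly = pre[idx]
            for j, i in enumerate(idx):
                if i in tangents and 0 < j < len(idx) - 1:
                    coords[i] = _project_to_polyline(coords[i], poly)
    return coords


def _project_to_polyline(p: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Closest point on a polyline to p."""
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    denom = (ab ** 2).sum(axis=1)
    denom[denom < 1e-300] = 1.0
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = ((proj - p) ** 2).sum(axis=1)
    return proj[np.argmin(d)]


def _canonical_orientation(aligned: np.ndarray, consensus: np.ndarray):
    """Rotate the whole fit to the consensus' principal axes (fixed signs).

    Axis signs follow the third moment (skewness) of the consensus along each
    axis — stable under perturbations, unlike a largest-coefficient rule.  An
    axis with (near-)zero skew, e.g. the left-right axis of a bilaterally
    symmetric shape, takes its sign from the det = +1 constraint instead.
    """
    c = consensus - consensus.mean(axis=0)
    cov = c.T @ c
    w, V = np.linalg.eigh(cov)
    V = V[:, ::-1]  # descending variance
    proj = c @ V
    skew = (proj ** 3).sum(axis=0)
    spread = np.maximum((proj ** 2).sum(axis=0) ** 1.5, 1e-300)
    rel = skew / spread
    signs = np.where(np.abs(rel) > 1e-9, np.sign(rel), 1.0)
    V = V * signs
    if np.linalg.det(V) < 0:
        V[:, np.argmin(np.abs(rel))] *= -1.0
    return aligned @ V, consensus @ V


def generalized_procrustes(
    configs: list[LandmarkConfiguration] | np.ndarray,
    slide: bool = True,
    tol: float = 1e-8,
    max_outer: int = 10,
    max_inner: int = 100,
    specimen_ids: list[str] | None = None,
    canonicalize: bool = True,
) -> ProcrustesFit:
    """Generalized Procrustes superimposition, optionally with sliding.

    ``configs`` may be LandmarkConfiguration objects (required for sliding) or
    a raw (n, k, 3) array.  Outer iterations interleave semilandmark sliding
    with full re-superimposition; convergence is declared when the consensus
    moves by less than ``tol`` (root-mean-square) between outer rounds.
    The output orientation is canonicalized to the consensus principal axes,
    making the fit invariant (to ``tol``) under arbitrary rigid motions and
    scalings of the inputs.
    """
    if isinstance(configs, np.ndarray):
        coords = np.asarray(configs, dtype=float).copy()
        config_objs = None
    else:
        config_objs = list(configs)
        coords = np.stack([c.coords for c in config_objs]).astype(float)
        if specimen_ids is None:
            specimen_ids = [None] * len(config_objs)
    n, k, _ = coords.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if config_objs is not None and any(c.k != k for c in config_objs):
        raise ValueError("all configurations must have the same number of points")

    sizes = np.array([centroid_size(c) for c in coords])
    X = np.stack([_center_scale(c) for c in coords])

    def superimpose(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        consensus = _center_scale(X[0])
        for _ in range(max_inner):
            for i in range(n):
                X[i] = X[i] @ optimal_rotation(X[i], consensus)
            new = X.mean(axis=0)
            new = _center_scale(new)
            if np.sqrt(((new - consensus) ** 2).mean()) < tol:
                consensus = new
                break
            consensus = new
        return X, consensus

    def total_ss(X, consensus):
        return float(((X - consensus[None]) ** 2).sum())

    X, consensus = superimpose(X)
    ss_history = [total_ss(X, consensus)]
    n_outer = 0
    converged = True
    if slide and config_objs is not None:
        converged = False
        for n_outer in range(1, max_outer + 1):
            prev = consensus.copy()
            for i in range(n):
                X[i] = _center_scale(
                    slide_semilandmarks(config_objs[i], X[i], consensus)
                )
            X, consensus = superimpose(X)
            ss_history.append(total_ss(X, consensus))
            if np.sqrt(((consensus - prev) ** 2).mean()) < tol:
                converged = True
                break
    if canonicalize:
        X, consensus = _canonical_orientation(X, consensus)
    return ProcrustesFit(
        aligned=X,
        consensus=X.mean(axis=0),
        centroid_sizes=sizes,
        n_slide_iterations=n_outer,
        converged=converged,
        specimen_ids=specimen_ids,
        ss_history=ss_history,
    )


def bilateral_symmetry(
    fit: ProcrustesFit | np.ndarray, config: LandmarkConfiguration
) -> SymmetryDecomposition:
    """Object-symmetry decomposition into symmetric + asymmetric components.

    For each specimen the configuration is reflected, the left/right paired
    labels are swapped, the mirrored copy is superimposed back on the
    original with a proper rotation, and the two are averaged.
    """
    aligned = fit.aligned if isinstance(fit, ProcrustesFit) else np.asarray(fit, float)
    k = aligned.shape[1]
    paired = set(config.side_pairing)
    mid = set(config.midline_idx.tolist())
    un = set(range(k)) - paired - mid
    if un:
        raise ValueError(f"unpaired non-midline points: {sorted(un)[:10]}")
    relabel = np.arange(k)
    for a, b in config.side_pairing.items():
        relabel[a] = b
    sym = np.empty_like(aligned)
    for i, X in enumerate(aligned):
        Xm = (X * np.array([1.0, -1.0, 1.0]))[relabel]
        Xm = Xm - Xm.mean(axis=0)
        Xm = Xm @ optimal_rotation(Xm, X)
        sym[i] = 0.5 * (X + Xm)
    return SymmetryDecomposition(symmetric=sym, asymmetric=aligned - sym)


def shape_pca(coords: np.ndarray) -> ShapeSpace:
    """PCA of (symmetric) shape coordinates.

    Eigendecomposition of the covariance of mean-centered flattened
    coordinates via SVD; components ordered by decreasing variance; the sign
    of each component is fixed so its largest-magnitude loading is positive.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 specimens")
    Y = coords.reshape(n, -1)
    mean = Y.mean(axis=0)
    Yc = Y - mean
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    nz = eig > max(eig.max(), 1e-300) * 1e-12
    eig = eig[nz]
    Vt = Vt[nz]
    scores = Yc @ Vt.T
    for j in range(Vt.shape[0]):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            Vt[j] = -Vt[j]
            scores[:, j] = -scores[:, j]
    pct = 100.0 * eig / eig.sum()
    return ShapeSpace(scores=scores, eigenvalues=eig, pct_variance=pct,
                      loadings=Vt, mean=mean)
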