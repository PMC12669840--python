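"""Contour curves and the fixed-landmark + semilandmark protocol.

A specimen is digitized as three labeled contour polylines on the upper bill
(maxillary rhamphotheca): the culmen (dorsal midline, bill tip to the proximal
end of the exposed culmen) and the left and right tomia (lateral cutting
edges).  Each curve is resampled to a fixed number of equally spaced points
(default 60) and the three curves are merged into one landmark configuration.
The shared bill-tip point is kept exactly once, so three n-point curves give
3n - 2 points (178 for n = 60): the four curve endpoints (tip + three proximal
ends) are homologous fixed landmarks, the rest are sliding semilandmarks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CURVE_LABELS = ("culmen", "left_tomium", "right_tomium")


@dataclass
class ContourCurve:
    """An ordered 3D polyline on the bill surface, stored tip-first.

    Parameters
    ----------
    label : str
        One of ``culmen``, ``left_tomium``, ``right_tomium``.
    points : (n, 3) ndarray
        Ordered coordinates in mm; the first point is the bill tip.
    """

    label: str
    points: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in CURVE_LABELS:
            raise ValueError(f"unknown curve label {self.label!r}")
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("contour points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("a contour needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError(f"curve {self.label!r} has coincident consecutive points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex (0 at the tip)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths()[-1])


@dataclass
class LandmarkConfiguration:
    """A k x 3 point configuration with landmark roles and curve structure.

    ``fixed_idx`` are homologous landmarks; ``semiland_idx`` slide along their
    curve during superimposition.  ``curve_membership`` maps each semilandmark
    index to ``(label, prev_idx, next_idx)`` — its within-curve neighbors used
    for tangent estimation.  ``side_pairing`` maps left-side point indices to
    their right-side mirror partners (an involution); ``midline_idx`` points
    lie on the sagittal plane and are unpaired.
    """

    coords: np.ndarray
    fixed_idx: np.ndarray
    semiland_idx: np.ndarray
    curve_membership: dict[int, tuple[str, int, int]]
    side_pairing: dict[int, int]
    midline_idx: np.ndarray
    curve_points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.fixed_idx = np.asarray(self.fixed_idx, dtype=int)
        self.semiland_idx = np.asarray(self.semiland_idx, dtype=int)
        self.midline_idx = np.asarray(self.midline_idx, dtype=int)
        k = len(self.coords)
        roles = np.concatenate([self.fixed_idx, self.semiland_idx])
        if sorted(roles.tolist()) != list(range(k)):
            raise ValueError("fixed_idx and semiland_idx must partition all points")
        for a, b in self.side_pairing.items():
            if self.side_pairing.get(b) != a:
                raise ValueError("side_pairing is not an involution")

    @property
    def k(self) -> int:
        return len(self.coords)

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        """Copy of this configuration with replaced coordinates."""
        return LandmarkConfiguration(
            coords=np.asarray(coords, dtype=float),
            fixed_idx=self.fixed_idx,
            semiland_idx=self.semiland_idx,
            curve_membership=self.curve_membership,
            side_pairing=self.side_pairing,
            midline_idx=self.midline_idx,
            curve_points=self.curve_points,
        )


def resample_curve(curve: ContourCurve, n: int = 60) -> ContourCurve:
    """Resample a polyline to ``n`` points equally spaced in arc length.

    Endpoints are preserved exactly; interior points are linearly interpolated
    on the original polyline.
    """
    if n < 2:
        raise ValueError("need n >= 2 resampled points")
    s = curve.arc_lengths()
    total = s[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-length curve")
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    out[0] = curve.points[0]
    out[-1] = curve.points[-1]
    for axis in range(3):
        out[1:-1, axis] = np.interp(targets[1:-1], s, curve.points[:, axis])
    return ContourCurve(label=curve.label, points=out)


def align_to_axis(
    contours: dict[str, ContourCurve],
    extra_points: np.ndarray | None = None,
) -> tuple[dict[str, ContourCurve], np.ndarray, np.ndarray]:
    """Rigidly align a specimen so the bill chord lies along +x.

    The chord runs from the bill tip (shared first point of the contours) to
    the proximal end of the culmen.  After alignment the tip sits at the
    origin, the chord points along +x, and the sagittal plane (spanned by the
    chord and the dorsal direction) is the x-z plane with left tomium at
    positive y.

    Returns the transformed contours, the rotation matrix R and translation t
    such that ``aligned = (p + t) @ R.T``; ``extra_points``, if given, are
    returned transformed in place of the contour dict's fourth element.
    """
    cul = contours["culmen"].points
    tip = cul[0]
    base = cul[-1]
    chord = base - tip
    cn = np.linalg.norm(chord)
    if cn < 1e-12:
        raise ValueError("tip and proximal culmen point coincide; no chord direction")
    xhat = chord / cn

    # Lateral direction from the tomium proximal ends; fall back to the
    # culmen sagittal plane if tomia are absent.
    lt = contours["left_tomium"].points[-1]
    rt = contours["right_tomium"].points[-1]
    yraw = lt - rt
    yraw = yraw - xhat * (yraw @ xhat)
    yn = np.linalg.norm(yraw)
    if yn < 1e-12:
        raise ValueError("cannot determine the sagittal plane: tomium ends degenerate")
    yhat = yraw / yn
    zhat = np.cross(xhat, yhat)
    R = np.vstack([xhat, yhat, zhat])  # rows: new axes; det = +1 by construction

    def tf(p: np.ndarray) -> np.ndarray:
        return (p - tip) @ R.T

    out = {
        lbl: ContourCurve(label=lbl, points=tf(c.points)) for lbl, c in contours.items()
    }
    if extra_points is not None:
        return out, R, tf(np.asarray(extra_points, dtype=float))
    return out, R, -R @ tip


def assemble_configuration(
    curves: dict[str, ContourCurve] | list[ContourCurve],
    tip_tolerance: float = 1e-6,
) -> LandmarkConfiguration:
    """Merge the three contour curves into one landmark configuration.

    All three curves must share the bill-tip point (their first points must
    coincide within ``tip_tolerance``).  The tip is kept once, assigned to the
    culmen/midline; left and right tomium points are paired by within-curve
    index for the bilateral-symmetry decomposition.
    """
    if not isinstance(curves, dict):
        curves = {c.label: c for c in curves}
    missing = [lbl for lbl in CURVE_LABELS if lbl not in curves]
    if missing:
        raise ValueError(f"missing contour curves: {missing}")
    cul, lt, rt = (curves[lbl] for lbl in CURVE_LABELS)
    if lt.n_points != rt.n_points:
        raise ValueError("left and right tomium must have equal point counts")
    tip = cul.points[0]
    for c in (lt, rt):
        if np.linalg.norm(c.points[0] - tip) > tip_tolerance:
            raise ValueError(
                f"curve {c.label!r} does not share the bill-tip point "
                f"(offset {np.linalg.norm(c.points[0] - tip):.3g} mm)"
            )

    n_c, n_t = cul.n_points, lt.n_points
    # Point order: culmen 0..n_c-1 (tip first), left tomium (minus tip),
    # right tomium (minus tip).
    coords = np.vstack([cul.points, lt.points[1:], rt.points[1:]])
    k = n_c + 2 * (n_t - 1)

    tip_i = 0
    cul_end = n_c - 1
    lt_idx = np.arange(n_c, n_c + n_t - 1)          # tomium index 1..n_t-1
    rt_idx = np.arange(n_c + n_t - 1, k)
    fixed = np.array([tip_i, cul_end, lt_idx[-1], rt_idx[-1]])
    semis = np.setdiff1d(np.arange(k), fixed)

    membership: dict[int, tuple[str, int, int]] = {}
    for j in range(1, n_c - 1):
        membership[j] = ("culmen", j - 1, j + 1)
    for arr, lbl in ((lt_idx, "left_tomium"), (rt_idx, "right_tomium")):
        full = np.concatenate([[tip_i], arr])  # tip is each tomium's first point
        for pos in range(1, len(full) - 1):
            membership[int(full[pos])] = (lbl, int(full[pos - 1]), int(full[pos + 1]))

    pairing: dict[int, int] = {}
    for a, b in zip(lt_idx, rt_idx):
        pairing[int(a)] = int(b)
        pairing[int(b)] = int(a)
    midline = np.arange(n_c)  # tip + culmen

    curve_points = {
        "culmen": np.arange(n_c),
        "left_tomium": np.concatenate([[tip_i], lt_idx]),
        "right_tomium": np.concatenate([[tip_i], rt_idx]),
    }
    return LandmarkConfiguration(
        coords=coords,
        fixed_idx=fixed,
        semiland_idx=semis,
        curve_membership=membership,
        side_pairing=pairing,
        midline_idx=midline,
        curve_points=curve_points,
    )


def configuration_from_contours(
    contours: dict[str, ContourCurve], n: int = 60
) -> LandmarkConfiguration:
    """Resample the three contours to ``n`` points each and assemble.

    Resampling can shift the shared tip only if the raw curves disagree; the
    tip tolerance scales with curve length to absorb digitization jitter.
    """
    res = {lbl: resample_curve(c, n) for lbl, c in contours.items()}
    tol = 1e-6 * max(c.length for c in res.values())
    # Digitization jitter can displace the three tip copies independently;
    # snap them to their common mean so the merge is exact.
    tips = np.array([res[lbl].points[0] for lbl in CURVE_LABELS])
    mean_tip = tips.mean(axis=0)
    for lbl in CURVE_LABELS:
        pts = res[lbl].points.copy()
        pts[0] = mean_tip
        res[lbl] = ContourCurve(label=lbl, points=pts)
    return assemble_configuration(res, tip_tolerance=max(tol, 1e-9))


# ---------------------------------------------------------------------------
# I/O

def write_configurations_csv(
    path: str | Path, configs: dict[str, LandmarkConfiguration]
) -> None:
    """Write landmark configurations as long-format CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["specimen_id", "point_index", "role", "curve_label", "x", "y", "z"])
        for sid, cfg in configs.items():
            roles = np.full(cfg.k, "semilandmark", dtype=object)
            roles[cfg.fixed_idx] = "fixed"
            labels = np.full(cfg.k, "", dtype=object)
            for lbl, idx in cfg.curve_points.items():
                labels[idx] = lbl
            labels[0] = "tip"
            for i, (x, y, z) in enumerate(cfg.coords):
                w.writerow([sid, i, roles[i], labels[i], f"{x:.9g}", f"{y:.9g}", f"{z:.9g}"])


def write_tps(path: str | Path, configs: dict[str, np.ndarray]) -> None:
    """Write 3D landmark coordinates in TPS dialect (LM3 blocks)."""
    with open(path, "w") as fh:
        for sid, coords in configs.items():
            coords = np.asarray(coords, dtype=float)
            fh.write(f"LM3={len(coords)}\n")
            for x, y, z in coords:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
            fh.write(f"ID={sid}\n")


def read_configurations_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Read coordinates back from the long-format CSV (coords only)."""
    rows: dict[str, list[tuple[int, float, float, float]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.setdefault(rec["specimen_id"], []).append(
                (int(rec["point_index"]), float(rec["x"]), float(rec["y"]), float(rec["z"]))
            )
    out = {}
    for sid, pts in rows.items():
        pts.sort()
        out[sid] = np.array([[x, y, z] for _, x, y, z in pts])
    return out
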