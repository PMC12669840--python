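"""GPA, sliding semilandmarks, bilateral symmetry, shape PCA."""

import numpy as np
import pytest

from billmech import (bilateral_symmetry, centroid_size, generalized_procrustes,
                      shape_pca, slide_semilandmarks)
from billmech.procrustes import _center_scale, optimal_rotation
from tests.conftest import make_config


def random_rotation(rng):
    Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


class TestCentroidSize:
    def test_unit_square(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        assert centroid_size(sq) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_scaling(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 3))
        assert centroid_size(3.7 * X) == pytest.approx(3.7 * centroid_size(X), rel=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            X = rng.standard_normal((7, 3)) * rng.uniform(0.1, 10)
            c = X.mean(axis=0)
            brute = np.sqrt(sum(np.sum((p - c) ** 2) for p in X))
            assert centroid_size(X) == pytest.approx(brute, rel=1e-12)


class TestGPA:
    def test_similarity_pair_distance_zero(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 3))
        Y = 2.5 * X @ random_rotation(rng).T + [1.0, -2.0, 0.5]
        fit = generalized_procrustes(np.stack([X, Y]), slide=False)
        assert np.linalg.norm(fit.aligned[0] - fit.aligned[1]) < 1e-9

    def test_identical_configs_consensus(self):
        X = np.random.default_rng(4).standard_normal((9, 3))
        fit = generalized_procrustes(np.stack([X, X, X]), slide=False)
        for a in fit.aligned:
            assert np.allclose(a, fit.consensus, atol=1e-10)

    def test_two_config_closed_form_oracle(self):
        """GPA of two 3-point configs matches the SVD ordinary-Procrustes oracle."""
        rng = np.random.default_rng(5)
        A = rng.standard_normal((3, 3))
        B = rng.standard_normal((3, 3))
        fit = generalized_procrustes(np.stack([A, B]), slide=False, canonicalize=False)
        d_gpa = np.linalg.norm(fit.aligned[0] - fit.aligned[1])
        # oracle: center+scale both, optimal proper rotation of B onto A
        Ac, Bc = _center_scale(A), _center_scale(B)
        M = Bc.T @ Ac
        U, s, Vt = np.linalg.svd(M)
        d = np.sign(np.linalg.det(U @ Vt))
        trace = s[0] + s[1] + d * s[2]
        d_oracle = np.sqrt(max(2.0 - 2.0 * trace, 0.0))
        assert d_gpa == pytest.approx(d_oracle, abs=1e-9)

    def test_unit_centroid_size_and_origin(self, small_population):
        from billmech.landmarks import configuration_from_contours
        from billmech import align_to_axis

        cfgs = []
        for sp in small_population[:6]:
            aligned, _, _ = align_to_axis(sp.contours)
            cfgs.append(configuration_from_contours(aligned, 15))
        fit = generalized_procrustes(cfgs)
        for a in fit.aligned:
            assert abs(centroid_size(a) - 1.0) < 1e-8
            assert np.allclose(a.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(fit.consensus, fit.aligned.mean(axis=0), atol=1e-12)

    def test_invariance_to_input_similarity_transforms(self):
        """Rigid motions + scalings of the inputs leave the fit unchanged."""
        cfgs = [make_config(15, jitter=0.05, seed=s) for s in range(6)]
        fit0 = generalized_procrustes(cfgs)
        rng = np.random.default_rng(17)
        moved = []
        for c in cfgs:
            Q = random_rotation(rng)
            s = rng.uniform(0.3, 3.0)
            moved.append(c.with_coords(s * c.coords @ Q.T + rng.standard_normal(3)))
        fit1 = generalized_procrustes(moved)
        assert np.allclose(fit0.aligned, fit1.aligned, atol=1e-8)

    def test_residuals_non_increasing_over_outer_iterations(self):
        cfgs = [make_config(20, jitter=0.08, seed=s) for s in range(8)]
        fit = generalized_procrustes(cfgs)
        ss = np.array(fit.ss_history)
        assert np.all(np.diff(ss) <= 1e-9 * ss[0])

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            generalized_procrustes([make_config(10), make_config(12)])

    def test_zero_size_rejected(self):
        X = np.zeros((2, 5, 3))
        with pytest.raises(ValueError):
            generalized_procrustes(X, slide=False)


class TestSliding:
    def test_projection_onto_tangent(self):
        cfg = make_config(15)
        coords = cfg.coords.copy()
        i = int(cfg.semiland_idx[3])
        _, prv, nxt = cfg.curve_membership[i]
        t = coords[nxt] - coords[prv]
        t /= np.linalg.norm(t)
        # consensus point on the tangent line, within the displacement cap
        cap = 0.4 * min(np.linalg.norm(coords[i] - coords[prv]),
                        np.linalg.norm(coords[nxt] - coords[i]))
        consensus = coords.copy()
        consensus[i] = coords[i] + cap * t
        slid = slide_semilandmarks(cfg, coords, consensus, reproject=False)
        assert np.allclose(slid[i], consensus[i], atol=1e-12)

    def test_orthogonal_residual_no_motion(self):
        cfg = make_config(15)
        coords = cfg.coords.copy()
        i = int(cfg.semiland_idx[5])
        _, prv, nxt = cfg.curve_membership[i]
        t = coords[nxt] - coords[prv]
        t /= np.linalg.norm(t)
        perp = np.cross(t, [0.0, 0.0, 1.0])
        perp -= t * (perp @ t)
        perp /= np.linalg.norm(perp)
        consensus = coords.copy()
        consensus[i] = coords[i] + 0.3 * perp
        slid = slide_semilandmarks(cfg, coords, consensus, reproject=False)
        assert np.allclose(slid[i], coords[i], atol=1e-12)

    def test_sliding_never_increases_distance_to_consensus(self):
        """Monotonicity over 100 random jittered configurations."""
        consensus = make_config(15).coords
        for s in range(100):
            cfg = make_config(15, jitter=0.05, seed=s)
            before = np.sum((cfg.coords - consensus) ** 2)
            slid = slide_semilandmarks(cfg, cfg.coords, consensus, reproject=False)
            after = np.sum((slid - consensus) ** 2)
            assert after <= before + 1e-12

    def test_reprojection_stays_on_polyline(self):
        cfg = make_config(20, jitter=0.02, seed=1)
        consensus = make_config(20).coords
        slid = slide_semilandmarks(cfg, cfg.coords, consensus, reproject=True)
        # every slid semilandmark lies on a segment of its source polyline
        for lbl, idx in cfg.curve_points.items():
            poly = cfg.coords[idx]
            for i in idx[1:-1]:
                seg = poly[1:] - poly[:-1]
                rel = slid[i] - poly[:-1]
                t = np.einsum("ij,ij->i", rel, seg) / np.einsum("ij,ij->i", seg, seg)
                t = np.clip(t, 0, 1)
                d = np.linalg.norm(rel - t[:, None] * seg, axis=1).min()
                assert d < 1e-9


class TestBilateralSymmetry:
    def test_symmetric_config_zero_asymmetry(self):
        cfg = make_config(20)  # noise-free: exactly symmetric by construction
        fit = np.stack([cfg.coords - cfg.coords.mean(0)])
        dec = bilateral_symmetry(fit, cfg)
        assert np.allclose(dec.asymmetric, 0.0, atol=1e-12)
        assert np.allclose(dec.symmetric, fit, atol=1e-12)

    def test_symmetric_component_is_mirror_fixed_point(self):
        cfg = make_config(15, jitter=0.05, seed=2)
        X = cfg.coords - cfg.coords.mean(axis=0)
        dec = bilateral_symmetry(np.stack([X]), cfg)
        relabel = np.arange(cfg.k)
        for a, b in cfg.side_pairing.items():
            relabel[a] = b
        S = dec.symmetric[0]
        Sm = (S * [1.0, -1.0, 1.0])[relabel]
        Sm = Sm - Sm.mean(axis=0)
        Sm = Sm @ optimal_rotation(Sm, S)
        assert np.allclose(Sm, S, atol=1e-9)

    def test_reconstruction(self):
        cfg = make_config(15, jitter=0.05, seed=3)
        X = np.stack([cfg.coords - cfg.coords.mean(axis=0)])
        dec = bilateral_symmetry(X, cfg)
        assert np.allclose(dec.symmetric + dec.asymmetric, X, atol=1e-12)

    def test_planted_left_displacement_splits_evenly(self):
        cfg = make_config(20)
        X = cfg.coords.copy()
        left = [i for i in cfg.side_pairing
                if cfg.coords[i, 1] > 0][3]
        delta = 1e-3
        X[left] += [0.0, 0.0, delta]
        X -= X.mean(axis=0)
        dec = bilateral_symmetry(np.stack([X]), cfg)
        mag = np.linalg.norm(dec.asymmetric[0, left])
        assert mag == pytest.approx(delta / 2, rel=0.02)

    def test_unpaired_nonmidline_rejected(self):
        cfg = make_config(10)
        bad = dict(cfg.side_pairing)
        a, b = next(iter(bad.items()))
        del bad[a], bad[b]
        cfg2 = cfg.with_coords(cfg.coords)
        cfg2.side_pairing = bad
        with pytest.raises(ValueError):
            bilateral_symmetry(np.stack([cfg.coords]), cfg2)


class TestShapePCA:
    def test_single_direction_100pct(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal((10, 3))
        direction = rng.standard_normal((10, 3))
        coords = np.stack([base + t * direction for t in np.linspace(-1, 1, 7)])
        space = shape_pca(coords)
        assert space.pct_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_reconstruction(self):
        rng = np.random.default_rng(9)
        coords = rng.standard_normal((6, 8, 3))
        space = shape_pca(coords)
        rec = space.scores @ space.loadings + space.mean
        assert np.allclose(rec, coords.reshape(6, -1), atol=1e-9)

    def test_pct_variance_sums_to_100_and_orthonormal(self):
        rng = np.random.default_rng(10)
        coords = rng.standard_normal((12, 20, 3))
        space = shape_pca(coords)
        assert space.pct_variance.sum() == pytest.approx(100.0, abs=1e-6)
        G = space.loadings @ space.loadings.T
        assert np.allclose(G, np.eye(len(G)), atol=1e-9)
        assert np.all(space.eigenvalues >= 0)
        assert np.all(np.diff(space.eigenvalues) <= 1e-12)

    def test_planted_mode_recovered(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal((15, 3))
        mode = rng.standard_normal(45)
        mode /= np.linalg.norm(mode)
        groups = np.repeat([-1.0, 1.0], 8)
        coords = np.stack([
            (base.ravel() + g * 0.5 * mode + 0.01 * rng.standard_normal(45)).reshape(15, 3)
            for g in groups
        ])
        space = shape_pca(coords)
        r = abs(np.corrcoef(space.loadings[0], mode)[0, 1])
        assert r > 0.99
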