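"""Superposition tests; the independent oracle is Horn's quaternion method."""

import math

import numpy as np
import pytest

from petprofiler.seq_align import AlignmentMap
from petprofiler.superpose import (
    FitError, apply_transform, kabsch, superpose_structures,
)
from petprofiler.synthetic_data import GeneratorConfig, make_ideal_structure, perturb_torsions

from test_geometry import random_rigid


def quaternion_rmsd(P, Q):
    """Optimal-superposition RMSD via the eigenvalues of Horn's 4x4 matrix.

    Independent of the SVD route: the largest eigenvalue lambda of the
    quaternion key matrix gives rmsd^2 = (|P|^2 + |Q|^2 - 2*lambda) / n
    after centering.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    n = len(P)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    S = Pc.T @ Qc
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    K = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    ssd = (Pc ** 2).sum() + (Qc ** 2).sum() - 2.0 * lam
    return math.sqrt(max(ssd, 0.0) / n)


class TestKabsch:
    def test_self_superposition(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(8, 3))
        r = kabsch(P, P)
        assert r.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(r.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(r.translation, 0.0, atol=1e-10)

    def test_exact_rigid_recovery(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(10, 3))
        theta = math.pi / 2
        R0 = np.array([[math.cos(theta), -math.sin(theta), 0],
                       [math.sin(theta), math.cos(theta), 0],
                       [0, 0, 1]])
        t0 = np.array([1.0, 2.0, 3.0])
        Q = P @ R0.T + t0
        r = kabsch(P, Q)
        assert r.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(r.rotation, R0, atol=1e-9)
        np.testing.assert_allclose(r.translation, t0, atol=1e-9)

    def test_quaternion_oracle_agreement(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            P = rng.normal(size=(10, 3))
            Q = rng.normal(size=(10, 3))
            assert kabsch(P, Q).rmsd == pytest.approx(quaternion_rmsd(P, Q),
                                                      abs=1e-9)

    def test_rotation_always_proper(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            R = kabsch(P, Q).rotation
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)

    def test_rigid_pretransform_invariance(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(12, 3))
        Q = rng.normal(size=(12, 3))
        ref = kabsch(P, Q).rmsd
        for _ in range(10):
            R, t = random_rigid(rng)
            assert kabsch(P @ R.T + t, Q).rmsd == pytest.approx(ref, abs=1e-9)
            assert kabsch(P, Q @ R.T + t).rmsd == pytest.approx(ref, abs=1e-9)

    def test_rmsd_symmetry(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(9, 3))
        Q = rng.normal(size=(9, 3))
        assert kabsch(P, Q).rmsd == pytest.approx(kabsch(Q, P).rmsd, abs=1e-12)

    def test_weighted_fit_downweights_outlier(self):
        rng = np.random.default_rng(6)
        P = rng.normal(size=(10, 3))
        Q = P.copy()
        Q[0] += 10.0
        w = np.ones(10)
        w[0] = 0.0
        r = kabsch(P, Q, weights=w)
        # with the outlier weightless the remaining points fit exactly
        d = P[1:] @ r.rotation.T + r.translation - Q[1:]
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(FitError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_cloud_rejected(self):
        P = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(FitError):
            kabsch(P, P + 1.0)


class TestSuperposeStructures:
    def test_self_identity_map(self, helix30):
        r = superpose_structures(helix30, helix30)
        assert r.rmsd == pytest.approx(0.0, abs=1e-12)
        assert r.n_used == r.n_initial == 30

    def test_trimming_excludes_displaced_loop(self, helix30):
        # homolog whose "loop" residues 10-14 are rigidly displaced by 5 A:
        # with trim_factor 2 the displaced pairs fall outside the core fit
        from copy import deepcopy
        moved = deepcopy(helix30)
        for res in moved.chain("A"):
            if 10 <= res.author_number <= 14:
                for atom in res.backbone.values():
                    atom.coords = atom.coords + np.array([5.0, 0.0, 0.0])
        amap = AlignmentMap.identity(30)
        untrimmed = superpose_structures(helix30, moved, amap,
                                         trim_factor=math.inf)
        trimmed = superpose_structures(helix30, moved, amap,
                                       trim_factor=2.0, max_iter=5)
        assert trimmed.n_used == 25
        assert trimmed.rmsd < untrimmed.rmsd
        assert trimmed.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_no_trim_limit_equals_plain_kabsch(self, helix30):
        moved = perturb_torsions(helix30, range(10, 15), 20.0,
                                 GeneratorConfig(seed=10))
        r = superpose_structures(helix30, moved, trim_factor=math.inf)
        direct = kabsch(helix30.ca_coords("A"), moved.ca_coords("A"))
        assert r.rmsd == pytest.approx(direct.rmsd, abs=1e-12)
        assert r.n_used == r.n_initial

    def test_too_few_mapped_pairs(self, helix30):
        amap = AlignmentMap(pairs=[(1, 1), (2, 2)])
        with pytest.raises(FitError):
            superpose_structures(helix30, helix30, amap)


class TestApplyTransform:
    def test_group_inverse(self, helix30):
        rng = np.random.default_rng(12)
        R, t = random_rigid(rng)
        moved = apply_transform(helix30, _as_result(R, t))
        back = apply_transform(moved, _as_result(R.T, -R.T @ t))
        np.testing.assert_allclose(back.ca_coords("A"), helix30.ca_coords("A"),
                                   atol=1e-9)

    def test_rmsd_consistent_after_apply(self, helix30):
        moved = perturb_torsions(helix30, range(10, 15), 20.0,
                                 GeneratorConfig(seed=13))
        r = superpose_structures(helix30, moved, trim_factor=math.inf)
        fitted = apply_transform(helix30, r)
        d = fitted.ca_coords("A") - moved.ca_coords("A")
        recomputed = math.sqrt(float((d ** 2).sum(axis=1).mean()))
        assert recomputed == pytest.approx(r.rmsd, abs=1e-9)

    def test_composition_is_matrix_product(self, helix30):
        rng = np.random.default_rng(14)
        R1, t1 = random_rigid(rng)
        R2, t2 = random_rigid(rng)
        two_step = apply_transform(apply_transform(helix30, _as_result(R1, t1)),
                                   _as_result(R2, t2))
        combined = apply_transform(helix30, _as_result(R2 @ R1, R2 @ t1 + t2))
        np.testing.assert_allclose(two_step.ca_coords("A"),
                                   combined.ca_coords("A"), atol=1e-9)


def _as_result(R, t):
    from petprofiler.superpose import SuperpositionResult
    return SuperpositionResult(rotation=R, translation=t, rmsd=0.0,
                               n_used=0, n_initial=0)
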