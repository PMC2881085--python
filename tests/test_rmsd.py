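"""Superposition, signatures, and the lower/upper bound machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from decoyclust import (
    compute_signature,
    precompute_metrics,
    rmsd,
    rmsd_matrix,
    rmsd_one_to_many,
    rrmsd,
    signature_distance,
    superpose,
)

TOY_A = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [5.0, 3.0, 1.0], [2.0, 4.0, -2.0]])
TOY_B = np.array([[0.5, -0.2, 0.1], [3.5, 1.0, -0.5], [6.0, 2.5, 0.8], [1.5, 4.5, -1.0]])


def rotation_space_oracle(a, b, n_grid=4000, seed=0):
    """Minimum RMSD over rotations: dense quaternion grid + local refinement.

    Independent of the SVD path: evaluates the deviation directly for
    explicit rotations after centroid alignment.
    """
    P = a - a.mean(axis=0)
    Q = b - b.mean(axis=0)

    def dev(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_grid, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rotvecs = Rotation.from_quat(quats).as_rotvec()
    vals = [dev(v) for v in rotvecs]
    best = rotvecs[int(np.argmin(vals))]
    res = minimize(dev, best, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14})
    return res.fun


class TestSuperpose:
    def test_identity(self, rng):
        a = rng.normal(size=(8, 3))
        assert superpose(a, a).rmsd < 1e-9

    def test_rigid_copy_is_zero(self, rng):
        a = rng.normal(size=(12, 3))
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        b = a @ R.T + np.array([5.0, -2.0, 1.0])
        assert superpose(a, b).rmsd < 1e-8

    def test_rotation_is_proper(self, rng):
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        res = superpose(a, b)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_translation_maps_centroids(self, rng):
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        res = superpose(a, b)
        assert np.allclose(res.transform(a).mean(axis=0), b.mean(axis=0), atol=1e-9)

    def test_toy_pair_matches_rotation_space_oracle(self):
        assert superpose(TOY_A, TOY_B).rmsd == pytest.approx(
            rotation_space_oracle(TOY_A, TOY_B), abs=1e-6
        )

    def test_random_pairs_match_biopython(self, rng):
        from Bio.SVDSuperimposer import SVDSuperimposer

        sup = SVDSuperimposer()
        for _ in range(10):
            a, b = rng.normal(size=(15, 3)), rng.normal(size=(15, 3))
            sup.set(b, a)  # biopython fits the second argument onto the first
            sup.run()
            assert superpose(a, b).rmsd == pytest.approx(sup.get_rms(), abs=1e-9)

    def test_unequal_lengths_raise(self, rng):
        with pytest.raises(ValueError, match="length"):
            superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_collinear_input_still_minimizes(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        assert superpose(line, line[::-1]).rmsd < 1e-8

    def test_invariant_under_joint_rigid_transform(self, rng):
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        R = Rotation.from_euler("xyz", [10, 60, -30], degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        assert superpose(a @ R.T + t, b @ R.T + t).rmsd == pytest.approx(
            superpose(a, b).rmsd, abs=1e-8
        )

    def test_batched_matches_scalar(self, rng):
        a = rng.normal(size=(9, 3))
        batch = rng.normal(size=(20, 9, 3))
        batched = rmsd_one_to_many(a, batch)
        for k in range(20):
            assert batched[k] == pytest.approx(rmsd(a, batch[k]), abs=1e-10)


class TestSignature:
    def test_symmetric_configuration(self):
        pts = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        assert np.allclose(compute_signature(pts), [1, 1, 1, 1])

    def test_translation_invariance(self, rng):
        a = rng.normal(size=(7, 3))
        assert np.allclose(compute_signature(a), compute_signature(a + 10.0), atol=1e-9)

    def test_naive_oracle_five_points(self, rng):
        a = rng.normal(size=(5, 3))
        centroid = sum(a[i] for i in range(5)) / 5.0
        expected = [np.sqrt(sum((a[i, k] - centroid[k]) ** 2 for k in range(3))) for i in range(5)]
        assert np.allclose(compute_signature(a), expected, atol=1e-12)

    def test_distance_hand_arithmetic(self):
        assert signature_distance([1.0, 1.0], [3.0, 1.0]) == pytest.approx(np.sqrt(2.0))
        assert signature_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_distance_length_mismatch(self):
        with pytest.raises(ValueError):
            signature_distance([1.0], [1.0, 2.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        arrays(float, (6, 3), elements=st.floats(-50, 50)),
        st.floats(0, 2 * np.pi),
        arrays(float, (3,), elements=st.floats(-100, 100)),
    )
    def test_rigid_invariance_property(self, coords, angle, shift):
        R = Rotation.from_euler("y", angle).as_matrix()
        assert np.allclose(
            compute_signature(coords), compute_signature(coords @ R.T + shift), atol=1e-8
        )

    def test_lower_bounds_rmsd_on_random_pairs(self, small_ensemble, small_matrix, rng):
        decoys, _ = small_ensemble
        sigs = [compute_signature(c) for c in decoys.coords]
        pairs = rng.choice(len(decoys), size=(200, 2))
        for x, y in pairs:
            assert signature_distance(sigs[x], sigs[y]) <= small_matrix[x, y] + 1e-9


class TestPrecomputedMetrics:
    def test_single_decoy(self, rng):
        coords = rng.normal(size=(1, 6, 3))
        m = precompute_metrics(coords, m_refs=1)
        assert np.allclose(m.ref_distances, 0.0)
        assert np.allclose(m.oriented[0], coords[0] - coords[0].mean(axis=0))

    def test_m_refs_clamped_with_warning(self, rng):
        coords = rng.normal(size=(2, 5, 3))
        with pytest.warns(UserWarning, match="clamp"):
            m = precompute_metrics(coords, m_refs=5)
        assert m.ref_distances.shape == (2, 2)

    def test_ref_distances_recomputable(self, small_ensemble):
        decoys, _ = small_ensemble
        m = precompute_metrics(decoys)
        for k, o in enumerate(m.ref_indices):
            for x in [0, 17, 55, 99]:
                assert m.ref_distances[x, k] == pytest.approx(
                    rmsd(decoys.coords[x], decoys.coords[int(o)]), abs=1e-9
                )

    def test_rrmsd_to_anchor_is_exact(self, small_ensemble):
        decoys, _ = small_ensemble
        m = precompute_metrics(decoys)
        for x in [3, 42, 77]:
            assert rrmsd(m, x, m.anchor) == pytest.approx(
                rmsd(decoys.coords[x], decoys.coords[m.anchor]), abs=1e-9
            )
        assert rrmsd(m, 5, 5) == 0.0

    def test_rrmsd_upper_bounds_rmsd(self, small_ensemble, small_matrix, rng):
        decoys, _ = small_ensemble
        m = precompute_metrics(decoys)
        pairs = rng.choice(len(decoys), size=(100, 2))
        for x, y in pairs:
            assert rrmsd(m, x, y) >= small_matrix[x, y] - 1e-9

    def test_sandwich(self, small_ensemble, small_matrix, rng):
        """max(lower bounds) <= RMSD <= min(upper bounds) on random pairs."""
        decoys, _ = small_ensemble
        m = precompute_metrics(decoys)
        pairs = rng.choice(len(decoys), size=(500, 2))
        for x, y in pairs:
            yy = np.array([y])
            lo = max(m.ref_lower(x, yy)[0], m.sig_lower(x, yy)[0])
            hi = min(m.ref_upper(x, yy)[0], m.rrmsd_many(x, yy)[0])
            assert lo <= small_matrix[x, y] + 1e-9
            assert small_matrix[x, y] <= hi + 1e-9


class TestMetricProperties:
    def test_symmetry_and_triangle_inequality(self, small_ensemble, small_matrix, rng):
        decoys, _ = small_ensemble
        for x, y in rng.choice(len(decoys), size=(50, 2)):
            assert rmsd(decoys.coords[x], decoys.coords[y]) == pytest.approx(
                rmsd(decoys.coords[y], decoys.coords[x]), abs=1e-9
            )
        triples = rng.choice(len(decoys), size=(500, 3))
        D = small_matrix
        for x, y, z in triples:
            assert D[x, z] <= D[x, y] + D[y, z] + 1e-7

    def test_matrix_agrees_with_scalar_path(self, rng):
        coords = rng.normal(size=(6, 8, 3))
        D = rmsd_matrix(coords)
        for i, j in itertools.combinations(range(6), 2):
            assert D[i, j] == pytest.approx(rmsd(coords[i], coords[j]), abs=1e-10)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
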