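"""Assembly RMSD, Kabsch superposition, simple and reference algorithms."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lmalign import (
    Assembly,
    PerturbationSpec,
    assembly_rmsd,
    center_assembly,
    kabsch_superpose,
    make_ladder_assembly,
    perturb,
    reference_superpose,
    rotation_matrix,
    simple_superpose,
)
from lmalign.errors import (
    ChainIDMismatchError,
    DimensionMismatchError,
    PermutationGuardError,
)
from lmalign.synthetic import random_rotation_quaternion


class TestAssemblyRmsd:
    def test_self_is_zero(self, ladder4):
        assert assembly_rmsd(ladder4, ladder4, np.arange(4)) == 0.0

    def test_single_point_pair(self):
        x = Assembly(coords=np.zeros((1, 1, 3)), chain_ids=("A",))
        y = Assembly(coords=np.array([[[5.0, 0.0, 0.0]]]), chain_ids=("A",))
        assert assembly_rmsd(x, y, np.array([0])) == pytest.approx(5.0)

    def test_matches_double_loop(self, rng):
        x = Assembly(coords=rng.normal(size=(4, 5, 3)), chain_ids="ABCD")
        y = Assembly(coords=rng.normal(size=(4, 5, 3)), chain_ids="ABCD")
        P = rng.permutation(4)
        acc = 0.0
        for k in range(4):
            for l in range(5):
                acc += np.sum((x.coords[k, l] - y.coords[P[k], l]) ** 2)
        expected = np.sqrt(acc / 20)
        assert assembly_rmsd(x, y, P) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self, ladder4):
        other = make_ladder_assembly(4, 5)
        with pytest.raises(DimensionMismatchError):
            assembly_rmsd(ladder4, other, np.arange(4))


class TestKabsch:
    def test_exact_recovery_of_applied_rotation(self, ladder4, rng):
        R_true = rotation_matrix(random_rotation_quaternion(rng))
        y = ladder4.with_coords(ladder4.coords @ R_true.T)
        res = kabsch_superpose(ladder4, y, np.arange(4))
        assert res.rmsd <= 1e-8
        np.testing.assert_allclose(res.R @ R_true, np.eye(3), atol=1e-8)

    def test_mirror_image_cannot_reach_zero(self, random_assembly):
        mirrored = random_assembly.with_coords(random_assembly.coords * [1, 1, -1])
        res = kabsch_superpose(random_assembly, mirrored, np.arange(3))
        assert np.linalg.det(res.R) == pytest.approx(1.0, abs=1e-12)
        assert res.rmsd > 0.5

    def test_beats_random_rotations(self, random_assembly, rng):
        y = Assembly(coords=rng.normal(scale=5, size=(3, 5, 3)), chain_ids="ABC")
        y, _ = center_assembly(y)
        P = np.arange(3)
        res = kabsch_superpose(random_assembly, y, P)
        samples = Rotation.random(1000, rng=123).as_matrix()
        for R in samples:
            trial = assembly_rmsd(random_assembly, y.with_coords(y.coords @ R.T), P)
            assert res.rmsd <= trial + 1e-12

    def test_agrees_with_scipy_align_vectors(self, random_assembly, rng):
        y = Assembly(coords=rng.normal(scale=5, size=(3, 5, 3)), chain_ids="ABC")
        y, _ = center_assembly(y)
        res = kabsch_superpose(random_assembly, y, np.arange(3))
        rot, _ = Rotation.align_vectors(random_assembly.points, y.points)
        np.testing.assert_allclose(res.R, rot.as_matrix(), atol=1e-8)

    def test_translation_recovers_original_frame(self, ladder4, rng):
        R_true = rotation_matrix(random_rotation_quaternion(rng))
        t_true = rng.uniform(-30, 30, 3)
        y = ladder4.with_coords(ladder4.coords @ R_true.T + t_true)
        res = kabsch_superpose(ladder4, y, np.arange(4))
        moved = y.coords @ res.R.T + res.t
        assert np.sqrt(np.mean(np.sum((moved - ladder4.coords) ** 2, -1))) <= 1e-8


class TestSimple:
    def test_identical_assemblies(self, ladder4):
        assert simple_superpose(ladder4, ladder4).rmsd <= 1e-12

    def test_permuted_copy_penalized(self, ladder4):
        y, _ = perturb(ladder4, PerturbationSpec(permutation=np.array([1, 0, 3, 2])))
        rs = simple_superpose(ladder4, y).rmsd
        rr = reference_superpose(ladder4, y).rmsd
        assert rr <= 1e-8
        assert rs > rr + 1.0

    def test_chain_id_mismatch(self, ladder4):
        other = Assembly(coords=ladder4.coords, chain_ids=("W", "X", "Y", "Z"))
        with pytest.raises(ChainIDMismatchError):
            simple_superpose(ladder4, other)

    def test_never_beats_reference(self):
        from lmalign import make_pair

        for seed in range(8):
            x, y, _ = make_pair(4, 6, noise_sd=0.5, seed=seed,
                                nontrivial_permutation=False)
            assert simple_superpose(x, y).rmsd >= reference_superpose(x, y).rmsd - 1e-9


class TestReference:
    def test_examines_all_24_mappings_for_tetramer(self, ladder4):
        res = reference_superpose(ladder4, ladder4)
        assert res.extras["n_mappings"] == 24

    def test_guard_refuses_decamer(self):
        a = make_ladder_assembly(10, 3)
        with pytest.raises(PermutationGuardError, match="3,628,800"):
            reference_superpose(a, a)

    def test_guard_overridable(self):
        a = make_ladder_assembly(9, 2)
        with pytest.raises(PermutationGuardError):
            reference_superpose(a, a)
        assert reference_superpose(a, a, max_N=9).rmsd <= 1e-12

    def test_recovers_inverse_permutation(self, ladder4, rng):
        perm = np.array([2, 0, 3, 1])
        spec = PerturbationSpec(
            permutation=perm,
            rotation=random_rotation_quaternion(rng),
            translation=rng.uniform(-10, 10, 3),
        )
        y, truth = perturb(ladder4, spec)
        res = reference_superpose(ladder4, y)
        assert res.rmsd <= 1e-8
        np.testing.assert_array_equal(res.mapping, truth.true_mapping)
        np.testing.assert_array_equal(res.mapping, np.argsort(perm))

    def test_invariant_under_relabeling_and_rigid_transform(self, ladder4, rng):
        from lmalign import make_pair

        x, y, _ = make_pair(4, 6, noise_sd=0.5, seed=11)
        base = reference_superpose(x, y).rmsd
        y2 = Assembly(coords=y.coords[[3, 1, 0, 2]], chain_ids="ABCD")
        assert abs(reference_superpose(x, y2).rmsd - base) <= 1e-8
        R = rotation_matrix(random_rotation_quaternion(rng))
        y3 = y.with_coords(y.coords @ R.T + rng.uniform(-40, 40, 3))
        assert abs(reference_superpose(x, y3).rmsd - base) <= 1e-8

    def test_role_exchange_symmetry(self):
        from lmalign import make_pair

        x, y, _ = make_pair(3, 6, noise_sd=0.4, seed=5)
        assert reference_superpose(x, y).rmsd == pytest.approx(
            reference_superpose(y, x).rmsd, abs=1e-8
        )
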