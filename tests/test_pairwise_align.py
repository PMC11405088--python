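import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from binderclust import (
    ChainStructure,
    align_sequences,
    all_vs_all,
    kabsch,
    make_fold,
    structural_align,
    tm_d0,
)
from binderclust.pairwise_align import AlignmentTable, alignment_identity_coverage

AA = "ACDEFGHIKLMNPQRSTVWY"


def _chain(coords, seq=None, cid="A"):
    n = len(coords)
    if seq is None:
        seq = ("ACDEFGHIKLMNPQRSTVWY" * (n // 20 + 1))[:n]
    return ChainStructure(cid, seq, np.asarray(coords, float), np.arange(1, n + 1))


class TestAlignSequences:
    def test_self_alignment_is_identity(self):
        corr = align_sequences("MKTAYIAKQR", "MKTAYIAKQR")
        assert corr.pairs == tuple((i, i) for i in range(10))

    def test_single_deletion(self):
        # frozen from the exhaustive dynamic program on this pair
        corr = align_sequences("ACDEFG", "ACEFG")
        assert corr.pairs == ((0, 0), (1, 1), (3, 2), (4, 3), (5, 4))

    def test_all_mismatch(self):
        corr = align_sequences("AAAA", "CCCC")
        assert len(corr) <= 4
        ident, _, _ = alignment_identity_coverage("AAAA", "CCCC")
        assert ident == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_sequences("", "ACD")

    def test_indices_strictly_increasing(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=rng.integers(5, 40)))
            b = "".join(rng.choice(list(AA), size=rng.integers(5, 40)))
            i1, i2 = align_sequences(a, b).as_arrays()
            assert np.all(np.diff(i1) > 0) and np.all(np.diff(i2) > 0)


class TestKabsch:
    def test_identical_points(self, rng):
        P = rng.normal(size=(10, 3))
        sup, rmsd = kabsch(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_exact_rigid_motion_recovered(self, rng):
        P = rng.normal(size=(12, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = (P - np.array([5.0, 0.0, 0.0])) @ R  # P = R @ Q + t
        sup, rmsd = kabsch(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.apply(Q), P, atol=1e-9)

    def test_rotation_is_proper(self, rng):
        for _ in range(10):
            sup, _ = kabsch(rng.normal(size=(8, 3)), rng.normal(size=(8, 3)))
            assert np.allclose(sup.rotation.T @ sup.rotation, np.eye(3), atol=1e-8)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTmD0:
    def test_closed_form_at_100(self):
        assert tm_d0(100) == pytest.approx(1.24 * (100 - 15) ** (1 / 3) - 1.8, abs=1e-9)

    def test_clamped_at_short_lengths(self):
        assert tm_d0(15) == 0.5
        assert tm_d0(1) == 0.5

    def test_nondecreasing(self):
        values = [tm_d0(L) for L in range(1, 1001)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestStructuralAlign:
    def test_self_alignment(self):
        s = _chain(make_fold(0, 40))
        res = structural_align(s, s)
        assert res.tm_1 == pytest.approx(1.0, abs=1e-9)
        assert res.tm_2 == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.coverage == 1.0

    def test_same_fold_under_noise(self, rng):
        fold = make_fold(2, 120)
        a = _chain(fold + rng.normal(scale=0.5, size=fold.shape))
        b = _chain(fold + rng.normal(scale=0.5, size=fold.shape))
        res = structural_align(a, b)
        assert res.tm_1 >= 0.9
        assert res.rmsd <= 1.5

    def test_helix_vs_hairpin_is_different_fold(self, rng):
        s1 = "".join(rng.choice(list(AA), size=40))
        s2 = "".join(rng.choice(list(AA), size=40))
        res = structural_align(_chain(make_fold(0, 40), s1), _chain(make_fold(1, 40), s2))
        assert min(res.tm_1, res.tm_2) < 0.5

    def test_rigid_invariance_of_rmsd(self, rng):
        fold = make_fold(0, 50)
        a = _chain(fold + rng.normal(scale=0.3, size=fold.shape))
        b = _chain(fold + rng.normal(scale=0.3, size=fold.shape))
        base = structural_align(a, b).rmsd
        R = Rotation.from_euler("xyz", [20, 45, 70], degrees=True).as_matrix()
        t = np.array([3.0, -7.0, 11.0])
        moved_a = _chain(a.ca_coords @ R.T + t, a.sequence)
        moved_b = _chain(b.ca_coords @ R.T + t, b.sequence)
        assert structural_align(moved_a, moved_b).rmsd == pytest.approx(base, abs=1e-9)

    def test_equal_lengths_give_equal_tms(self, rng):
        fold = make_fold(1, 36)
        a = _chain(fold + rng.normal(scale=0.4, size=fold.shape))
        b = _chain(fold + rng.normal(scale=0.4, size=fold.shape))
        res = structural_align(a, b)
        assert res.tm_1 == pytest.approx(res.tm_2, abs=1e-12)

    def test_refinement_near_exhaustive_optimum(self, rng):
        """On tiny chains, the iterative subset refinement lands within 5%
        of the best RMSD over all pair subsets of the same size."""
        import itertools

        for trial in range(5):
            n = 6
            coords = np.cumsum(3.8 * rng.normal(size=(n, 3)), axis=0)
            a = _chain(coords, "ACDEFG")
            b = _chain(coords + rng.normal(scale=1.0, size=coords.shape), "ACDEFG")
            res = structural_align(a, b)
            k = int(np.sum(
                np.linalg.norm(
                    res.superposition.apply(b.ca_coords) - a.ca_coords, axis=1
                ) < max(4.5, tm_d0(n))
            ))
            k = max(k, 3)
            best = min(
                kabsch(a.ca_coords[list(sub)], b.ca_coords[list(sub)])[1]
                for sub in itertools.combinations(range(n), k)
            )
            assert res.rmsd <= 1.05 * best + 1e-9


class TestAllVsAll:
    def _members(self, rng, n=5):
        fold = make_fold(0, 30)
        seq = "".join(rng.choice(list(AA), size=30))
        return [
            (f"m{i}", _chain(fold + rng.normal(scale=0.4, size=fold.shape), seq))
            for i in range(n)
        ]

    def test_pair_count(self, rng):
        table = all_vs_all(self._members(rng, 3))
        assert len(table.results) == 3

    def test_diagonal_is_trivial_self_alignment(self, rng):
        table = all_vs_all(self._members(rng, 3))
        res = table.result_for("m1", "m1")
        assert res.tm_1 == 1.0 and res.rmsd == 0.0

    def test_symmetric_views(self, rng):
        table = all_vs_all(self._members(rng, 5))
        for i in range(5):
            for j in range(5):
                a = table.result_for(f"m{i}", f"m{j}")
                b = table.result_for(f"m{j}", f"m{i}")
                assert a.rmsd == pytest.approx(b.rmsd, abs=1e-9)
                assert a.tm_1 == pytest.approx(b.tm_2, abs=1e-12)

    def test_cpu_count_does_not_change_results(self, rng):
        members = self._members(rng, 6)
        df1 = all_vs_all(members, cpus=1).to_dataframe()
        df4 = all_vs_all(members, cpus=4).to_dataframe()
        assert df1.equals(df4)

    def test_save_load_round_trip(self, rng, tmp_path):
        table = all_vs_all(self._members(rng, 4))
        table.save(tmp_path / "t.csv", tmp_path / "t.json")
        back = AlignmentTable.load(tmp_path / "t.csv", tmp_path / "t.json")
        for key, res in table.results.items():
            other = back.results[key]
            assert other.rmsd == pytest.approx(res.rmsd, rel=1e-12)
            assert other.n_pairs == res.n_pairs
            assert np.allclose(other.superposition.rotation, res.superposition.rotation)
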