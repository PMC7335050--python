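import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_average_linkage, quaternion_rmsd

from groovemapper.ensemble import (
    AtomMask,
    Ensemble,
    average_linkage_cluster,
    compare_sites,
    default_mask,
    kabsch_superpose,
    pairwise_rmsd,
    read_ensemble,
    read_ensemble_pdb,
    read_ensemble_table,
    top_population,
    write_ensemble_pdb,
    write_ensemble_table,
)
from groovemapper.synthetic import EnsembleSpec, gen_ensemble, make_separated_centers


def random_matrix(rng, n):
    A = rng.uniform(0.1, 10.0, (n, n))
    D = (A + A.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def rigid_copy(X, rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return X @ R.T + rng.uniform(-15, 15, 3)


class TestMask:
    def test_default_mask(self):
        mask = default_mask()
        assert mask.residues("receptor") == list(range(102, 126)) + list(range(147, 178))
        assert mask.residues("peptide") == list(range(4, 24))
        assert mask.n_atoms == 24 + 31 + 20

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            AtomMask(segments=(("receptor", 1, 10), ("receptor", 5, 12)))

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            AtomMask(segments=(("peptide", 10, 5),))


class TestEnsembleIO:
    def test_table_roundtrip(self, tmp_path, rng):
        ens = Ensemble(frames=rng.normal(size=(4, 7, 3)))
        path = write_ensemble_table(ens, tmp_path / "ens.dat")
        back = read_ensemble_table(path)
        assert back.frames.shape == (4, 7, 3)
        np.testing.assert_allclose(back.frames, ens.frames, atol=1e-3)

    def test_pdb_roundtrip_with_mask(self, tmp_path, rng):
        mask = AtomMask(segments=(("receptor", 5, 9), ("peptide", 1, 3)))
        ens = Ensemble(frames=rng.normal(scale=8, size=(3, 8, 3)), mask=mask)
        path = write_ensemble_pdb(ens, tmp_path / "ens.pdb")
        back = read_ensemble_pdb(path, mask=mask)
        assert back.frames.shape == (3, 8, 3)
        np.testing.assert_allclose(back.frames, ens.frames, atol=2e-3)

    def test_pdb_missing_masked_residue_errors(self, tmp_path, rng):
        mask = AtomMask(segments=(("receptor", 5, 9), ("peptide", 1, 3)))
        ens = Ensemble(frames=rng.normal(scale=8, size=(2, 8, 3)), mask=mask)
        path = write_ensemble_pdb(ens, tmp_path / "ens.pdb")
        wider = AtomMask(segments=(("receptor", 5, 10), ("peptide", 1, 3)))
        with pytest.raises(ValueError, match="model 0 missing CA of receptor residue 10"):
            read_ensemble_pdb(path, mask=wider)

    def test_read_deterministic(self, tmp_path, rng):
        ens = Ensemble(frames=rng.normal(size=(3, 5, 3)))
        path = write_ensemble_table(ens, tmp_path / "ens.dat")
        a = read_ensemble(path)
        b = read_ensemble(path)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_dispatch_by_extension(self, tmp_path, rng):
        mask = AtomMask(segments=(("receptor", 1, 4),))
        ens = Ensemble(frames=rng.normal(scale=5, size=(2, 4, 3)), mask=mask)
        p1 = write_ensemble_pdb(ens, tmp_path / "e.pdb")
        assert read_ensemble(p1, mask=mask).n_frames == 2


class TestKabsch:
    def test_rigid_transform_zero_rmsd(self, rng):
        X = rng.normal(size=(10, 3))
        Y = rigid_copy(X, rng)
        R, t, rmsd = kabsch_superpose(X, Y)
        assert rmsd <= 1e-8
        np.testing.assert_allclose(X @ R.T + t, Y, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(20):
            X = rng.normal(size=(8, 3))
            Y = rng.normal(size=(8, 3))
            assert kabsch_superpose(X, Y)[2] == pytest.approx(
                kabsch_superpose(Y, X)[2], abs=1e-10
            )

    def test_quaternion_oracle_agreement(self, rng):
        for _ in range(100):
            X = rng.normal(size=(10, 3))
            Y = rng.normal(size=(10, 3))
            assert kabsch_superpose(X, Y)[2] == pytest.approx(
                quaternion_rmsd(X, Y), abs=1e-8
            )

    def test_reflection_excluded(self, rng):
        X = rng.normal(size=(12, 3))
        Y = X.copy()
        Y[:, 0] *= -1  # mirror image
        R, _, rmsd = kabsch_superpose(X, Y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1  # cannot be undone by a proper rotation

    def test_degenerate_collinear(self):
        X = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(X, X)

    def test_shape_check(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestPairwiseRMSD:
    def test_matches_exact_kabsch(self, rng):
        ens = Ensemble(frames=rng.normal(scale=4, size=(12, 9, 3)))
        D = pairwise_rmsd(ens)
        for i in range(12):
            for j in range(i + 1, 12):
                assert D[i, j] == pytest.approx(
                    kabsch_superpose(ens.frames[i], ens.frames[j])[2], abs=1e-6
                )

    def test_symmetric_zero_diagonal(self, rng):
        ens = Ensemble(frames=rng.normal(scale=4, size=(10, 8, 3)))
        D = pairwise_rmsd(ens)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_duplicated_frame_zero_entry(self, rng):
        frames = rng.normal(scale=4, size=(6, 8, 3))
        frames[4] = frames[1]
        D = pairwise_rmsd(Ensemble(frames=frames))
        assert D[1, 4] <= 1e-7

    def test_rigid_motion_invariance(self, rng):
        frames = rng.normal(scale=4, size=(8, 10, 3))
        D1 = pairwise_rmsd(Ensemble(frames=frames))
        # one global transform applied to every frame
        rngg = np.random.default_rng(5)
        q = rngg.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        D2 = pairwise_rmsd(Ensemble(frames=frames @ R.T + np.array([3.0, -2.0, 7.0])))
        np.testing.assert_allclose(D1, D2, atol=1e-7)

    def test_triangle_violations_counted_exhaustively(self):
        from itertools import combinations

        from groovemapper.ensemble import triangle_violation_fraction

        # metric matrix: no violations
        pts = np.random.default_rng(3).normal(size=(9, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        assert triangle_violation_fraction(D) == 0.0
        # break one entry and compare against a brute-force triple count
        D2 = D.copy()
        D2[0, 1] = D2[1, 0] = D.max() * 3
        expected = 0
        for i, j, k in combinations(range(9), 3):
            a, b, c = D2[i, j], D2[i, k], D2[j, k]
            if 2 * max(a, b, c) > a + b + c + 1e-9:
                expected += 1
        total = len(list(combinations(range(9), 3)))
        assert triangle_violation_fraction(D2) == pytest.approx(expected / total)

    def test_two_center_jitter_free_values(self):
        centers = make_separated_centers(2, 8, 5.0, seed=2)
        spec = EnsembleSpec(
            n_frames=20, centers=centers, populations=[0.5, 0.5], jitter_sd=0.0
        )
        ens = gen_ensemble(spec, seed=3)
        D = pairwise_rmsd(ens)
        off = np.round(D[np.triu_indices(20, 1)], 6)
        assert len(set(off.tolist())) == 2  # zero and the center separation


class TestAverageLinkage:
    def test_epsilon_above_max_one_cluster(self, rng):
        D = random_matrix(rng, 15)
        res = average_linkage_cluster(D, epsilon=D.max() * 10)
        assert res.n_clusters == 1
        assert res.populations == [1.0]

    def test_epsilon_below_min_all_singletons(self, rng):
        D = random_matrix(rng, 15)
        res = average_linkage_cluster(D, epsilon=D[D > 0].min() / 2)
        assert res.n_clusters == 15
        assert res.populations[0] == pytest.approx(1 / 15)

    def test_matches_naive_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 40))
            D = random_matrix(rng, n)
            eps = float(rng.uniform(D[D > 0].min(), D.max()))
            mine = average_linkage_cluster(D, eps).labels
            ref = naive_average_linkage(D, eps)
            np.testing.assert_array_equal(mine, ref)

    def test_populations_partition(self, rng):
        D = random_matrix(rng, 30)
        res = average_linkage_cluster(D, epsilon=np.median(D))
        assert sum(res.populations) == pytest.approx(1.0)
        assert sorted(res.populations, reverse=True) == res.populations
        counts = np.bincount(res.labels)
        np.testing.assert_allclose(counts / 30, res.populations)

    def test_monotone_in_epsilon(self, rng):
        D = random_matrix(rng, 25)
        eps_grid = np.linspace(0.1, D.max() * 1.1, 12)
        ns = [average_linkage_cluster(D, e).n_clusters for e in eps_grid]
        assert all(b <= a for a, b in zip(ns, ns[1:]))

    def test_invalid_matrices(self):
        with pytest.raises(ValueError):
            average_linkage_cluster(np.array([[0.0, -1.0], [-1.0, 0.0]]), 1.0)
        with pytest.raises(ValueError):
            average_linkage_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]), 1.0)
        with pytest.raises(ValueError):
            average_linkage_cluster(np.zeros((2, 3)), 1.0)

    def test_medoid_representative(self):
        # 4 points: cluster {0,1,2} with 1 central, singleton {3}
        D = np.array(
            [
                [0.0, 1.0, 2.0, 50.0],
                [1.0, 0.0, 1.0, 50.0],
                [2.0, 1.0, 0.0, 50.0],
                [50.0, 50.0, 50.0, 0.0],
            ]
        )
        res = average_linkage_cluster(D, epsilon=3.0)
        assert res.n_clusters == 2
        assert res.representatives[0] == 1


class TestTopPopulation:
    def test_single_cluster(self, rng):
        D = random_matrix(rng, 10)
        res = average_linkage_cluster(D, epsilon=D.max() * 2)
        pop, medoid = top_population(res)
        assert pop == 1.0
        assert 0 <= medoid < 10

    def test_recovers_design_population(self):
        centers = make_separated_centers(2, 10, 5.0, seed=7)
        spec = EnsembleSpec(
            n_frames=600, centers=centers, populations=[0.65, 0.35],
            jitter_sd=0.25, rigid_transform=True,
        )
        ens = gen_ensemble(spec, seed=8)
        res = average_linkage_cluster(pairwise_rmsd(ens), epsilon=2.0)
        pop, _ = top_population(res)
        truth = np.bincount(ens.true_labels).max() / ens.n_frames
        assert pop == pytest.approx(truth, abs=1e-12)  # clean separation: exact


class TestCompareSites:
    def _make(self, pops, seed, n_frames=400):
        centers = make_separated_centers(len(pops), 10, 5.0, seed=seed)
        return gen_ensemble(
            EnsembleSpec(n_frames=n_frames, centers=centers, populations=pops,
                         jitter_sd=0.2, rigid_transform=True),
            seed=seed + 100,
        )

    def test_ranking_correct_disjoint(self):
        report = compare_sites(
            {"canonical": self._make([0.75, 0.25], 1),
             "noncanonical": self._make([0.35, 0.33, 0.32], 2)},
            epsilon=2.0, seed=5,
        )
        names = [e["name"] for e in report["ranking"]]
        assert names == ["canonical", "noncanonical"]
        assert report["conclusive"]

    def test_identical_ensembles_inconclusive(self):
        ens = self._make([0.6, 0.4], 3)
        report = compare_sites({"a": ens, "b": ens}, epsilon=2.0, seed=5)
        assert not report["conclusive"]
        assert report["warnings"]

    def test_bootstrap_reproducible(self):
        ensembles = {"a": self._make([0.7, 0.3], 4), "b": self._make([0.5, 0.5], 5)}
        r1 = compare_sites(ensembles, epsilon=2.0, seed=9)
        r2 = compare_sites(ensembles, epsilon=2.0, seed=9)
        assert r1 == r2
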