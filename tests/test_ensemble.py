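"""Ensemble analysis: selection, RMSD, clustering, maps, Rg."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cldmd.ensemble import (
    SnapshotSet,
    choose_cutoff,
    contact_frequency,
    contact_map,
    daura_cluster,
    fraction_native_contacts,
    kabsch_rmsd,
    radius_of_gyration,
    relax_unconstrained,
    rmsd_matrix,
    rmsf,
    select_low_energy,
)


def _random_structures(rng, m, n=12, spread=1.0):
    base = rng.normal(0, 5, size=(n, 3))
    return np.stack([base + rng.normal(0, spread, size=(n, 3))
                     for _ in range(m)])


class TestSelectLowEnergy:
    def test_keeps_floor_fraction(self, rng):
        snaps = SnapshotSet(rng.normal(size=(100, 5, 3)), rng.normal(size=100))
        sel = select_low_energy(snaps, 0.10)
        assert len(sel) == 10
        assert sel.energies.max() <= np.sort(snaps.energies)[10]

    def test_fraction_one_is_identity(self, rng):
        snaps = SnapshotSet(rng.normal(size=(7, 5, 3)), rng.normal(size=7))
        sel = select_low_energy(snaps, 1.0)
        assert np.array_equal(sel.coords, snaps.coords)

    def test_equals_sort_and_slice(self, rng):
        energies = rng.normal(size=50)
        snaps = SnapshotSet(rng.normal(size=(50, 4, 3)), energies)
        sel = select_low_energy(snaps, 0.2)
        expected = set(np.argsort(energies, kind="stable")[:10])
        assert set(sel.sources) == expected

    def test_invalid_fraction(self, rng):
        snaps = SnapshotSet(rng.normal(size=(5, 4, 3)), rng.normal(size=5))
        with pytest.raises(ValueError):
            select_low_energy(snaps, 0.0)


def _quaternion_rmsd(A, B):
    """Independent oracle: Horn's quaternion superposition method."""
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    M = A0.T @ B0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    sq = ((A0**2).sum() + (B0**2).sum() - 2 * lam) / A.shape[0]
    return math.sqrt(max(sq, 0.0))


class TestKabschRmsd:
    def test_identical_structures(self, rng):
        A = rng.normal(size=(8, 3))
        assert kabsch_rmsd(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_gives_zero(self, rng):
        A = rng.normal(size=(9, 3))
        R = Rotation.random(random_state=3).as_matrix()
        B = A @ R.T + np.array([4.0, -2.0, 7.0])
        assert kabsch_rmsd(A, B) == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(25):
            A = rng.normal(size=(5, 3))
            B = rng.normal(size=(5, 3))
            assert kabsch_rmsd(A, B) == pytest.approx(
                _quaternion_rmsd(A, B), abs=1e-9
            )

    def test_no_reflection_used(self, rng):
        # mirror image: RMSD must stay positive (proper rotations only)
        A = rng.normal(size=(6, 3))
        B = A.copy()
        B[:, 0] *= -1
        assert kabsch_rmsd(A, B) > 0.1

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(10):
            A, B, C = (rng.normal(size=(7, 3)) for _ in range(3))
            ab, ba = kabsch_rmsd(A, B), kabsch_rmsd(B, A)
            assert ab == pytest.approx(ba, abs=1e-9)
            assert kabsch_rmsd(A, C) <= ab + kabsch_rmsd(B, C) + 1e-9

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestChooseCutoff:
    def test_two_structures(self, rng):
        structs = _random_structures(rng, 2)
        M = rmsd_matrix(structs)
        assert choose_cutoff(M) == pytest.approx(M[0, 1])

    def test_degenerate_distribution(self):
        M = np.full((5, 5), 2.5)
        np.fill_diagonal(M, 0.0)
        assert choose_cutoff(M) == pytest.approx(2.5)

    def test_bimodal_takes_taller_mode(self, rng):
        # synthetic distance matrix: a 14-blob and a 6-blob far apart; the
        # within-blob distances (106 pairs) outnumber the between-blob
        # ones (84 pairs), so the low-RMSD mode must win
        m = 20
        M = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                same = (i < 14) == (j < 14)
                M[i, j] = M[j, i] = (
                    rng.uniform(0.5, 0.7) if same else rng.uniform(8.0, 8.5)
                )
        cut = choose_cutoff(M)
        assert cut < 4.0


class TestDauraCluster:
    def _brute_force(self, M, cutoff):
        """Reference implementation: literal greedy neighbour counting."""
        remaining = list(range(len(M)))
        out = []
        while remaining:
            best, best_members = None, None
            for c in remaining:
                members = [j for j in remaining if M[c, j] <= cutoff]
                if best_members is None or len(members) > len(best_members):
                    best, best_members = c, members
            out.append((best, sorted(best_members)))
            remaining = [j for j in remaining if j not in set(best_members)]
        out.sort(key=lambda t: (-len(t[1]), t[1][0]))
        return out

    def test_all_within_cutoff(self, rng):
        structs = _random_structures(rng, 6, spread=0.1)
        M = rmsd_matrix(structs)
        cl = daura_cluster(M, 10.0)
        assert cl.n_clusters == 1 and cl.populations[0] == 1.0

    def test_all_beyond_cutoff(self, rng):
        structs = _random_structures(rng, 5, spread=4.0)
        M = rmsd_matrix(structs)
        cl = daura_cluster(M, 1e-6)
        assert cl.n_clusters == 5
        assert all(p == 0.2 for p in cl.populations)

    @pytest.mark.parametrize("m,cutoff", [(10, 1.5), (20, 2.0), (30, 2.5)])
    def test_equals_brute_force_reference(self, rng, m, cutoff):
        M = np.zeros((m, m))
        vals = rng.uniform(0.2, 5.0, size=(m, m))
        M = np.triu(vals, 1)
        M = M + M.T
        cl = daura_cluster(M, cutoff)
        ref = self._brute_force(M, cutoff)
        assert cl.centroids == [c for c, _ in ref]
        assert cl.clusters == [members for _, members in ref]

    def test_planted_blobs_recovered(self, rng):
        m = 20
        M = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                same = (i < 12) == (j < 12)
                M[i, j] = M[j, i] = (
                    rng.uniform(0.2, 0.8) if same else rng.uniform(6, 7)
                )
        cl = daura_cluster(M, 1.0)
        assert [len(c) for c in cl.clusters[:2]] == [12, 8]

    def test_populations_are_input_fractions(self, rng):
        M = rmsd_matrix(_random_structures(rng, 8))
        cl = daura_cluster(M, choose_cutoff(M))
        assert sum(cl.populations) == pytest.approx(1.0)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            daura_cluster(np.zeros((3, 3)), 0.0)

    def test_pipeline_permutation_invariance(self, rng):
        """select + cluster gives the same partition under frame shuffling."""
        structs = _random_structures(rng, 15, spread=0.8)
        energies = rng.normal(size=15)
        snaps = SnapshotSet(structs, energies)
        perm = rng.permutation(15)
        shuffled = SnapshotSet(structs[perm], energies[perm],
                               [int(p) for p in perm])
        def partition(s):
            sel = select_low_energy(s, 0.8)
            M = rmsd_matrix(sel.coords)
            cl = daura_cluster(M, 2.0)
            return sorted(
                tuple(sorted(sel.sources[k] for k in members))
                for members in cl.clusters
            )
        assert partition(snaps) == partition(shuffled)


class TestRmsf:
    def test_identical_members_zero(self, rng):
        base = rng.normal(size=(10, 3))
        members = np.stack([base] * 4)
        assert np.allclose(rmsf(members, base), 0.0, atol=1e-12)

    def test_jittered_residue_localized(self, rng):
        base = rng.normal(0, 5, size=(10, 3))
        d = 0.8
        members = []
        for sgn in (+1, -1, +1, -1):
            m = base.copy()
            m[4, 2] += sgn * d
            members.append(m)
        vals = rmsf(np.stack(members), base)
        assert vals[4] == pytest.approx(d, rel=0.2)
        assert np.all(vals[[0, 1, 2, 8, 9]] < 0.3)

    def test_member_rotation_invariance(self, rng):
        base = rng.normal(size=(10, 3))
        member = base + rng.normal(0, 0.3, size=(10, 3))
        R = Rotation.random(random_state=5).as_matrix()
        v1 = rmsf(np.stack([member, base]), base)
        v2 = rmsf(np.stack([member @ R.T + 3.0, base]), base)
        assert np.allclose(v1, v2, atol=1e-9)

    def test_single_member_rejected(self, rng):
        with pytest.raises(ValueError):
            rmsf(rng.normal(size=(1, 5, 3)), rng.normal(size=(5, 3)))


class TestContactMaps:
    def test_inclusive_eight_angstrom_convention(self):
        coords = np.zeros((8, 3))
        coords[:, 0] = np.arange(8) * 38.0
        coords[5] = coords[0] + np.array([7.9, 0, 0])
        cmap = contact_map(coords)
        assert cmap[0, 5] == 1.0 and cmap[5, 0] == 1.0

    def test_near_diagonal_band_excluded(self):
        coords = np.zeros((6, 3))
        coords[:, 0] = np.arange(6) * 3.8
        cmap = contact_map(coords)
        assert cmap[0, 1] == 0.0 and cmap[0, 2] == 0.0

    def test_frequency_is_member_mean(self, rng):
        base = np.zeros((8, 3))
        base[:, 0] = np.arange(8) * 38.0
        members = []
        for k in range(4):
            m = base.copy()
            if k < 3:
                m[6] = m[0] + np.array([7.0, 0, 0])
            members.append(m)
        freq = contact_frequency(np.stack(members))
        assert freq[0, 6] == pytest.approx(0.75)
        assert freq.min() >= 0.0 and freq.max() <= 1.0

    def test_single_member_equals_binary_map(self, rng):
        coords = rng.normal(0, 6, size=(10, 3))
        assert np.array_equal(
            contact_frequency(coords[None]), contact_map(coords)
        )

    def test_fraction_native_contacts_self_is_one(self, rng):
        coords = rng.normal(0, 4, size=(15, 3))
        q = fraction_native_contacts(coords, coords)
        assert q == 1.0 or math.isnan(q)


class TestRadiusOfGyration:
    def test_single_point(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_points(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_square_side_two(self):
        coords = np.array(
            [[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], dtype=float
        )
        assert radius_of_gyration(coords) == pytest.approx(math.sqrt(2.0))


class TestRelaxation:
    def test_discard_must_be_smaller_than_steps(self, small_model):
        from cldmd.engine import random_coil

        with pytest.raises(ValueError):
            relax_unconstrained(random_coil(10, 1), small_model,
                                n_steps=100, discard=100)

    def test_fixed_seed_identical_trace(self, small_model):
        from cldmd.engine import random_coil

        coords = random_coil(10, seed=6)
        runs = [
            relax_unconstrained(coords, small_model, n_steps=2000,
                                discard=500, seed=9)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0]["rg_trace"], runs[1]["rg_trace"])
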