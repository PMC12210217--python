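import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from peptoidsolv.conformation import (
    Conformation,
    aggregate_rg_series,
    end_to_end,
    featurize,
    radius_of_gyration,
    reconstruct,
    rmsd,
    rmsd_histogram,
)
from peptoidsolv.synthetic import make_backbone


def random_rigid(coords, seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 10, 3)
    return coords @ R.T + t


def brute_force_rmsd(P, Q, n_starts=40):
    """Independent oracle: minimise RMSD over rotation vectors numerically."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((Pc @ R.T - Qc) ** 2).sum() / len(P))

    rng = np.random.default_rng(7)
    best = np.inf
    for _ in range(n_starts):
        rv0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestRMSD:
    def test_identity_is_zero(self):
        c = make_backbone(shape="coiled_C")
        assert rmsd(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        c = make_backbone(shape="semi_open")
        moved = Conformation(random_rigid(c.coords, seed=1))
        assert rmsd(moved, c) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        a = make_backbone(shape="coiled_C", noise_sigma=0.5, seed=1)
        b = make_backbone(shape="extended", noise_sigma=0.5, seed=2)
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-9)

    def test_matches_brute_force_rotational_oracle(self):
        rng = np.random.default_rng(3)
        P = rng.normal(0, 3, (5, 3))  # asymmetric 5-atom toy
        Q = random_rigid(P, seed=4) + rng.normal(0, 0.7, (5, 3))
        assert rmsd(P, Q) == pytest.approx(brute_force_rmsd(P, Q), abs=1e-6)

    def test_uniform_displacement_after_alignment(self):
        rng = np.random.default_rng(5)
        P = rng.normal(0, 3, (5, 3))
        Q = P + np.array([1.0, 0.0, 0.0])  # pure translation of 1 A
        assert rmsd(P, Q) == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_mirror_image_not_matched_by_proper_rotation(self):
        rng = np.random.default_rng(6)
        P = rng.normal(0, 3, (8, 3))
        M = P * np.array([1, 1, -1])
        assert rmsd(P, M) > 0.1


class TestScalarMetrics:
    def test_rg_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_rg_two_equal_masses(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords, [1.0, 1.0]) == pytest.approx(1.0)

    def test_rg_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        r = rng.normal(0, 5, (10, 3))
        m = rng.uniform(1, 20, 10)
        com = (m[:, None] * r).sum(0) / m.sum()
        expected = np.sqrt((m * ((r - com) ** 2).sum(1)).sum() / m.sum())
        assert radius_of_gyration(r, m) == pytest.approx(expected, abs=1e-12)

    def test_rg_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((2, 3)), [1.0, 0.0])

    def test_end_to_end_collinear(self):
        chain = np.column_stack([1.5 * np.arange(10), np.zeros(10), np.zeros(10)])
        assert end_to_end(chain) == pytest.approx(13.5)

    def test_end_to_end_closed_ring(self):
        ring = np.vstack([np.eye(3), np.zeros(3), [1, 0, 0]])
        ring[0] = [1, 0, 0]
        assert end_to_end(ring) == 0.0

    def test_end_to_end_hits_generator_target(self):
        c = make_backbone(n_atoms=11, shape="extended", target_end_to_end=26.0)
        assert end_to_end(c) == pytest.approx(26.0, abs=1e-9)


class TestFeaturize:
    def test_rigid_invariance(self):
        c = make_backbone(shape="coiled_C", noise_sigma=0.2, seed=8)
        moved = Conformation(random_rigid(c.coords, seed=9))
        assert np.allclose(featurize(c), featurize(moved), atol=1e-9)

    def test_unit_tetrahedron(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                      [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]])
        F = featurize(v)
        assert np.allclose(F[F > 1e-12], 1.0, atol=1e-9)

    def test_matches_pairwise_distance_oracle(self):
        rng = np.random.default_rng(10)
        r = rng.normal(0, 4, (12, 3))
        F = featurize(r)
        for i in range(12):
            for j in range(3):
                assert F[i, j] == pytest.approx(np.linalg.norm(r[i] - r[j]), abs=1e-12)

    def test_collinear_anchors_warn(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        coords[3:] += [0, 1.0, 0.5]
        with pytest.warns(UserWarning, match="collinear"):
            featurize(coords)


class TestReconstruct:
    @pytest.mark.parametrize("shape", ["coiled_C", "semi_open", "extended"])
    def test_planar_roundtrip_exact(self, shape):
        c = make_backbone(shape=shape)
        rec = reconstruct(featurize(c))
        assert rmsd(rec, c) < 1e-9

    def test_helix_roundtrip_up_to_mirror(self):
        t = np.linspace(0, 4 * np.pi, 20)
        helix = np.column_stack([2 * np.cos(t), 2 * np.sin(t), t])
        helix *= 1.5 / np.linalg.norm(np.diff(helix, axis=0), axis=1).mean()
        rec = reconstruct(featurize(helix))
        mirror = helix * np.array([1, 1, -1])
        assert min(rmsd(rec, helix), rmsd(rec, mirror)) <= 1e-6

    def test_idempotent_on_mean_of_identical_features(self):
        c = make_backbone(shape="semi_open")
        F = featurize(c)
        rec = reconstruct(np.mean([F, F], axis=0))
        assert rmsd(rec, c) < 1e-9

    def test_infeasible_distances_flagged(self):
        c = make_backbone(shape="extended")
        F = featurize(c)
        F[5, 0] *= 0.2  # break triangle feasibility for atom 6
        rec = reconstruct(F)
        assert 5 in rec.meta["reconstruction_flags"]


class TestHistogramsAndSeries:
    def test_all_equal_gives_single_spike(self):
        ref = make_backbone(shape="coiled_C")
        confs = [Conformation(random_rigid(ref.coords, seed=i)) for i in range(5)]
        hist = rmsd_histogram(confs, ref, bin_width=0.5)
        edges, density = hist[""]
        assert density[0] == pytest.approx(2.0)  # all mass in [0, 0.5)

    def test_bimodal_families_land_in_expected_bins(self):
        rng = np.random.default_rng(11)
        ref = make_backbone(shape="coiled_C")
        near, far = [], []
        # displace every atom radially to plant approximate RMSD levels
        for i in range(30):
            near.append(Conformation(ref.coords + rng.normal(0, 2.0 / np.sqrt(3), ref.coords.shape)))
            far.append(Conformation(ref.coords + rng.normal(0, 8.0 / np.sqrt(3), ref.coords.shape)))
        hist = rmsd_histogram(near + far, ref, bin_width=1.0)
        edges, density = hist[""]
        values = [rmsd(c, ref) for c in near + far]
        assert np.histogram(values, bins=edges)[0].argsort()[-2:].min() < len(edges) // 2

    def test_densities_integrate_to_one(self):
        confs = [make_backbone(shape="coiled_C", noise_sigma=1.0, seed=i) for i in range(20)]
        ref = make_backbone(shape="coiled_C")
        for edges, density in rmsd_histogram(confs, ref).values():
            widths = np.diff(edges)
            assert (density * widths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_static_trajectory_has_zero_std(self):
        frame = make_backbone(shape="coiled_C").coords
        _, mean, std = aggregate_rg_series([frame, frame, frame])
        assert std == pytest.approx(0.0, abs=1e-12)

    def test_two_frame_summary(self):
        # planted Rg 10 and 12 via scaled rings of equal masses
        base = make_backbone(shape="coiled_C").coords
        rg0 = radius_of_gyration(base)
        series, mean, std = aggregate_rg_series([base * (10 / rg0), base * (12 / rg0)])
        assert mean == pytest.approx(11.0, abs=1e-9)
        assert std == pytest.approx(1.0, abs=1e-9)

    def test_tight_vs_loose_agglomerates_ordered(self):
        from peptoidsolv.synthetic import make_agglomerate_frames

        tight = make_agglomerate_frames(scale=0.7, seed=1)
        loose = make_agglomerate_frames(scale=1.3, seed=1)
        _, mean_t, _ = aggregate_rg_series(tight)
        _, mean_l, _ = aggregate_rg_series(loose)
        assert mean_t < mean_l

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            aggregate_rg_series([])
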