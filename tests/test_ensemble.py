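import numpy as np
import pytest
from hypothesis import given, strategies as st

from idpkit import ensemble as ens, synth
from idpkit.ensemble import KB_KJ_MOL_K, WeightedEnsemble


class TestReweight:
    def test_constant_bias_uniform(self):
        w = ens.reweight(np.full(7, 3.2), 283.0)
        np.testing.assert_allclose(w, 1.0 / 7)

    def test_two_frame_closed_form(self):
        T = 283.0
        v = np.array([0.0, KB_KJ_MOL_K * T * np.log(3.0)])
        np.testing.assert_allclose(ens.reweight(v, T), [0.25, 0.75])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=30))
    def test_normalization_and_stability(self, vals):
        w = ens.reweight(np.array(vals), 283.0)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)

    def test_nonfinite_bias_rejected(self):
        with pytest.raises(ValueError):
            ens.reweight(np.array([0.0, np.inf]))


class TestRadiusOfGyration:
    def test_coincident_points(self):
        assert ens.radius_of_gyration(np.zeros((4, 3))) == 0.0

    def test_two_points_half_distance(self):
        pts = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert ens.radius_of_gyration(pts) == pytest.approx(0.2)  # 2 Å = 0.2 nm

    def test_regular_polygon_equals_radius(self):
        # brute-force oracle: n points on a circle of radius R have Rg = R
        R, n = 7.0, 12
        th = 2 * np.pi * np.arange(n) / n
        pts = np.column_stack([R * np.cos(th), R * np.sin(th), np.zeros(n)])
        com = pts.mean(axis=0)
        oracle = np.sqrt(((pts - com) ** 2).sum(axis=1).mean()) / 10.0
        assert ens.radius_of_gyration(pts) == pytest.approx(oracle, rel=1e-12)
        assert ens.radius_of_gyration(pts) == pytest.approx(R / 10.0, rel=1e-12)

    def test_mass_weighting(self):
        pts = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        rg = ens.radius_of_gyration(pts, masses=np.array([3.0, 1.0]))
        # com at 1 Å: sqrt((3*1 + 1*9)/4) Å = sqrt(3) Å
        assert rg == pytest.approx(np.sqrt(3.0) / 10.0)

    def test_uniform_weighted_mean_equals_arithmetic(self, coil_ensemble):
        rg = ens.ensemble_rg(coil_ensemble)
        assert ens.weighted_mean(rg, coil_ensemble.weights) == pytest.approx(rg.mean())


class TestSecondaryStructure:
    def test_isolated_residues_unassigned(self):
        from idpkit.geometry import build_backbone

        xyz = build_backbone(np.array([-57.0, -57.0]), np.array([-47.0, -47.0]))
        ss = ens.assign_secondary_structure(xyz)
        assert list(ss) == ["-", "-"]

    def test_ideal_helix_interior_alpha(self, helix_ensemble):
        ss = ens.assign_secondary_structure(helix_ensemble.coords[0])
        assert (ss[1:-1] == "H").sum() >= 14

    def test_mixture_census_decomposition(self, helix_ensemble, coil_ensemble):
        """Census of a merged ensemble is the weight-mix of sub-censuses."""
        n = 25
        helix = helix_ensemble.coords[:, :n]
        coil = coil_ensemble.coords[:2]
        merged = WeightedEnsemble(np.concatenate([helix, coil]), ["ALA"] * n)
        c_h = ens.helix_census(WeightedEnsemble(helix, ["ALA"] * n))
        c_c = ens.helix_census(WeightedEnsemble(coil, ["ALA"] * n))
        w = helix.shape[0] / (helix.shape[0] + coil.shape[0])
        np.testing.assert_allclose(
            ens.helix_census(merged), w * c_h + (1 - w) * c_c, atol=1e-12
        )

    def test_census_matches_generator_truth(self):
        model = synth.HelixModel(
            n_residues=30, helix_region=(8, 23),
            p_nucleate=0.3, p_stay=0.9, dihedral_noise_deg=3.0, seed=21,
        )
        e = synth.gen_ensemble(model, n_frames=60)
        census = ens.helix_census(e)
        truth = e.helix_truth.mean(axis=0)
        interior = slice(9, 21)  # binomial error ~ 3/sqrt(60) plus edge effects
        assert np.all(np.abs(census[interior] - truth[interior]) < 0.2)


class TestContactMap:
    def test_sequential_neighbors_in_contact(self, coil_ensemble):
        cmap = ens.contact_map(coil_ensemble, cutoff=8.5, stride=1)
        first_off = np.diag(cmap, k=1)
        np.testing.assert_allclose(first_off, 1.0)  # d(i,i+1) ≈ 3.8 Å

    def test_diagonal_and_symmetry(self, coil_ensemble):
        cmap = ens.contact_map(coil_ensemble, stride=3)
        np.testing.assert_allclose(np.diag(cmap), 1.0)
        np.testing.assert_allclose(cmap, cmap.T)
        assert cmap.min() >= 0.0 and cmap.max() <= 1.0

    def test_two_frame_weighted_hand_example(self):
        # pair (0, 2) in contact in frame 0 only; weights (0.25, 0.75)
        coords = np.zeros((2, 3, 5, 3))
        for f in range(2):
            coords[f, 1, :, 0] = 5.0
            coords[f, 2, :, 0] = 8.0 if f == 0 else 20.0
        T = 283.0
        bias = np.array([0.0, KB_KJ_MOL_K * T * np.log(3.0)])
        e = WeightedEnsemble(coords, ["ALA"] * 3, bias=bias, temperature=T)
        cmap = ens.contact_map(e, cutoff=8.5, stride=1)
        assert cmap[0, 2] == pytest.approx(0.25)

    def test_monotone_in_cutoff(self, coil_ensemble):
        c_small = ens.contact_map(coil_ensemble, cutoff=6.0, stride=2)
        c_large = ens.contact_map(coil_ensemble, cutoff=8.5, stride=2)
        assert np.all(c_small <= c_large + 1e-12)


class TestContactLogRatio:
    def test_identical_maps_zero(self):
        m = np.random.default_rng(0).random((4, 4))
        out = ens.contact_log_ratio(m, m, pseudocount=0.01)
        np.testing.assert_allclose(out, 0.0)

    def test_doubling_gives_log2(self):
        ref = np.full((3, 3), 0.4)
        out = ens.contact_log_ratio(2 * ref, ref, pseudocount=1e-9)
        np.testing.assert_allclose(out, np.log(2.0), rtol=1e-6)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((4, 4)), rng.random((4, 4))
        fwd = ens.contact_log_ratio(a, b, pseudocount=0.05)
        rev = ens.contact_log_ratio(b, a, pseudocount=0.05)
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_default_pseudocount(self):
        out = ens.contact_log_ratio(np.zeros((2, 2)), np.zeros((2, 2)), n_frames_used=50)
        np.testing.assert_allclose(out, 0.0)


class TestBlockAverageError:
    def test_constant_series_zero_error(self):
        err, _, errors = ens.block_average_error(np.full(256, 3.0))
        assert err == 0.0
        np.testing.assert_allclose(errors, 0.0)

    def test_iid_recovers_sem(self):
        rng = np.random.default_rng(0)
        n = 2**14
        err, _, _ = ens.block_average_error(rng.normal(size=n))
        assert err == pytest.approx(1.0 / np.sqrt(n), rel=0.25)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ens.block_average_error(np.arange(5.0))

    def test_uniform_weights_match_unweighted(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1024)
        e1, _, c1 = ens.block_average_error(x)
        e2, _, c2 = ens.block_average_error(x, weights=np.ones_like(x))
        assert e1 == pytest.approx(e2, rel=1e-12)
        np.testing.assert_allclose(c1, c2)
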