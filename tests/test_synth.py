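"""Generator tests: forward models at zero noise are fixed points of the
corresponding fits, and every generator is a pure function of its seed."""

import numpy as np
import pytest
from scipy.optimize import brentq

from idpkit import binding, ensemble as ens, synth
from idpkit.composition import residue_frequencies
from idpkit.geometry import measure_dihedral


def mass_balance_csp(P0, L0, K_D, delta_max):
    """Independent oracle: solve the 1:1 mass balance numerically.

    [PL] is the root of (P0 - PL)(L0 - PL) = K_D * PL on [0, min(P0, L0)];
    the CSP is delta_max * [PL] / P0.
    """
    if L0 == 0:
        return 0.0
    f = lambda pl: (P0 - pl) * (L0 - pl) - K_D * pl
    pl = brentq(f, 0.0, min(P0, L0))
    return delta_max * pl / P0


class TestSequenceSets:
    def test_equal_frequencies_give_null_enrichment(self):
        f = synth.uniform_aa_frequencies()
        q, b = synth.gen_sequence_sets(f, f, n_seqs=1000, length_range=(100, 200), seed=0)
        fq = residue_frequencies(q)
        fb = residue_frequencies(b)
        enrich = (fq - fb) / fb
        # ~150k residues per set: sd(enrichment) ≈ 0.016, bound at ~4 sd
        assert np.all(np.abs(enrich) < 0.06)

    def test_law_of_large_numbers_frequencies(self):
        fq = synth.uniform_aa_frequencies(E=0.10)
        fb = synth.uniform_aa_frequencies(E=0.05)
        q, b = synth.gen_sequence_sets(
            fq, fb, n_seqs=2000, length_range=(200, 200), seed=1
        )
        assert abs(residue_frequencies(q)["E"] - 0.10) < 0.002
        assert abs(residue_frequencies(b)["E"] - 0.05) < 0.002

    def test_seed_determinism(self):
        f = synth.uniform_aa_frequencies(E=0.08)
        a = synth.gen_sequence_sets(f, f, n_seqs=10, seed=42)
        b = synth.gen_sequence_sets(f, f, n_seqs=10, seed=42)
        assert [r.sequence for r in a[0]] == [r.sequence for r in b[0]]
        assert [r.sequence for r in a[1]] == [r.sequence for r in b[1]]

    def test_negative_frequency_rejected(self):
        bad = dict(synth.uniform_aa_frequencies())
        bad["E"] += bad["A"] + 0.01
        bad["A"] = -0.01
        with pytest.raises(ValueError, match="negative"):
            synth.gen_sequence_sets(bad, synth.uniform_aa_frequencies(), n_seqs=2)


class TestTitration:
    def test_noiseless_matches_isotherm_exactly(self):
        truth = synth.TitrationGroundTruth(K_D=380.0, delta_max={"T39": 0.8})
        series = synth.gen_titration(truth)
        for _, row in series.data.iterrows():
            expected = binding.isotherm(truth.P0, row["L0_uM"], truth.K_D, 0.8)
            assert row["csp_ppm"] == pytest.approx(expected, abs=1e-12)

    def test_zero_ligand_gives_zero_csp(self):
        truth = synth.TitrationGroundTruth(
            K_D=100.0, delta_max={"A1": 1.0}, L0_list=(0.0, 100.0, 500.0, 1000.0)
        )
        series = synth.gen_titration(truth)
        assert series.data.iloc[0]["csp_ppm"] == 0.0

    def test_closed_form_against_mass_balance_oracle(self):
        # frozen from the numerical equilibrium solve
        assert binding.isotherm(50, 450, 380, 1.0) == pytest.approx(0.527152848, abs=1e-8)
        for L0 in (10.0, 450.0, 2000.0):
            oracle = mass_balance_csp(50.0, L0, 380.0, 1.0)
            assert binding.isotherm(50.0, L0, 380.0, 1.0) == pytest.approx(oracle, rel=1e-10)


class TestEnsembleGenerator:
    def test_no_nucleation_means_no_helix(self, coil_ensemble):
        assert coil_ensemble.helix_truth.sum() == 0
        census = ens.helix_census(coil_ensemble)
        assert census.max() <= 0.05

    def test_interior_of_forced_helix_assigned_helical(self):
        model = synth.HelixModel(
            n_residues=24, helix_region=(5, 20),
            p_nucleate=1.0, p_stay=1.0, dihedral_noise_deg=0.0, seed=3,
        )
        e = synth.gen_ensemble(model, n_frames=1)
        ss = ens.assign_secondary_structure(e.coords[0])
        # interior of the forced region (1-based 7..18) must be helical
        assert ens.is_helical(ss)[6:18].all()

    def test_helical_phi_within_noise_of_ideal(self):
        noise = 4.0
        model = synth.HelixModel(
            n_residues=15, helix_region=(1, 15),
            p_nucleate=1.0, p_stay=1.0, dihedral_noise_deg=noise, seed=5,
        )
        e = synth.gen_ensemble(model, n_frames=4)
        for f in range(e.n_frames):
            for i in range(1, 15):
                phi = measure_dihedral(
                    e.coords[f, i - 1, 2], e.coords[f, i, 0],
                    e.coords[f, i, 1], e.coords[f, i, 2],
                )
                assert abs(phi - (-57.0)) < 5 * noise

    def test_seed_determinism(self):
        model = synth.HelixModel(20, (5, 15), seed=9)
        a = synth.gen_ensemble(model, n_frames=3)
        b = synth.gen_ensemble(model, n_frames=3)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.helix_truth, b.helix_truth)


class TestBias:
    def test_constant_spec_all_equal(self, helix_ensemble):
        v = synth.gen_bias(helix_ensemble, bias_fn=lambda rg: np.full(rg.size, 3.0))
        assert np.all(v == 3.0)

    def test_default_quadratic_finite(self, coil_ensemble):
        v = synth.gen_bias(coil_ensemble)
        assert np.all(np.isfinite(v))
        assert v.shape == (coil_ensemble.n_frames,)

    def test_reproducible(self, coil_ensemble):
        np.testing.assert_array_equal(
            synth.gen_bias(coil_ensemble), synth.gen_bias(coil_ensemble)
        )


class TestScatteringGenerator:
    def test_zero_q_limit_is_I0(self):
        c = synth.gen_scattering(2.0, I0=7.0, q_grid=np.array([1e-6, 0.1, 0.2, 0.3, 0.4]))
        assert c.I[0] == pytest.approx(7.0, rel=1e-9)

    def test_noiseless_is_exact_guinier(self):
        c = synth.gen_scattering(2.0, I0=1.0)
        np.testing.assert_allclose(c.I, np.exp(-c.q**2 * 4.0 / 3.0), rtol=1e-12)


class TestDosyGenerator:
    def test_noiseless_is_exact_exponential_in_g2(self):
        c = synth.gen_dosy(1.0e-10)
        logI = np.log(c.I)
        # exactly linear in g^2
        coeffs = np.polyfit(c.g**2, logI, 1)
        resid = logI - np.polyval(coeffs, c.g**2)
        assert np.max(np.abs(resid)) < 1e-12

    def test_zero_gradient_point_is_I0(self):
        c = synth.gen_dosy(1e-10, gradient_strengths=np.array([1e-9, 0.1, 0.2, 0.3]), I0=2.5)
        assert c.I[0] == pytest.approx(2.5, rel=1e-9)
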