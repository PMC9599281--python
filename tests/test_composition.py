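import numpy as np
import pytest

from idpkit import composition, synth
from idpkit.io import SequenceRecord


def recs(*seqs, tag=None):
    return [SequenceRecord(f"s{i}", s, tag) for i, s in enumerate(seqs)]


class TestResidueFrequencies:
    def test_single_sequence(self):
        f = composition.residue_frequencies(recs("ACDE"))
        for aa in "ACDE":
            assert f[aa] == 0.25
        assert f.sum() == pytest.approx(1.0)

    def test_two_sequences(self):
        f = composition.residue_frequencies(recs("EE", "DD"))
        assert f["E"] == 0.5 and f["D"] == 0.5

    def test_pooling_invariance(self):
        a = composition.residue_frequencies(recs("MKLVE" + "GDDDF"))
        b = composition.residue_frequencies(recs("MKLVE", "GDDDF"))
        np.testing.assert_allclose(a.values, b.values)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            composition.residue_frequencies([])


class TestEnrichmentProfile:
    def test_identical_sets_null(self):
        seqs = recs("MKLVADE", "GGHHEE", "PPQQRR")
        prof = composition.enrichment_profile(seqs, seqs, n_boot=100, seed=0)
        present = prof["freq_background"] > 0
        assert np.allclose(prof.loc[present, "enrichment"], 0.0)
        assert not prof["significant"].any()

    def test_all_E_query_against_half_E_background(self):
        query = recs("EEEE", "EE")
        background = recs("ED", "EDED")
        prof = composition.enrichment_profile(query, background, n_boot=50, seed=0)
        assert prof.loc["E", "enrichment"] == pytest.approx(1.0)  # (1-0.5)/0.5

    def test_missing_background_residue_is_nan_with_warning(self, caplog):
        query = recs("EW")
        background = recs("ED")
        with caplog.at_level("WARNING"):
            prof = composition.enrichment_profile(query, background, n_boot=20, seed=0)
        assert np.isnan(prof.loc["W", "enrichment"])
        assert "W" in caplog.text

    def test_point_estimate_inside_ci(self):
        fq = synth.uniform_aa_frequencies(E=0.10)
        fb = synth.uniform_aa_frequencies(E=0.05)
        q, b = synth.gen_sequence_sets(fq, fb, n_seqs=100, seed=2)
        prof = composition.enrichment_profile(q, b, n_boot=400, seed=3)
        ok = prof["freq_background"] > 0
        assert (prof.loc[ok, "ci_low"] <= prof.loc[ok, "enrichment"]).all()
        assert (prof.loc[ok, "enrichment"] <= prof.loc[ok, "ci_high"]).all()

    def test_single_boot_identical_sets_zero_width(self):
        seqs = recs("MKLVADE", "GGHHEE")
        prof = composition.enrichment_profile(seqs, seqs, n_boot=1, seed=5)
        ok = prof["freq_background"] > 0
        widths = prof.loc[ok, "ci_high"] - prof.loc[ok, "ci_low"]
        assert np.allclose(widths, 0.0)

    def test_ci_width_shrinks_with_more_sequences(self):
        fq = synth.uniform_aa_frequencies(E=0.10)
        fb = synth.uniform_aa_frequencies(E=0.05)
        widths = []
        for n in (30, 300):
            q, b = synth.gen_sequence_sets(fq, fb, n_seqs=n, seed=4)
            prof = composition.enrichment_profile(q, b, n_boot=300, seed=4)
            widths.append(prof.loc["E", "ci_high"] - prof.loc["E", "ci_low"])
        assert widths[1] < widths[0]

    def test_antisymmetry_closed_forms(self):
        q = recs("EEED")  # f_q(E)=0.75
        b = recs("EDDD")  # f_b(E)=0.25
        p_qb = composition.enrichment_profile(q, b, n_boot=10, seed=0)
        p_bq = composition.enrichment_profile(b, q, n_boot=10, seed=0)
        assert p_qb.loc["E", "enrichment"] == pytest.approx((0.75 - 0.25) / 0.25)
        assert p_bq.loc["E", "enrichment"] == pytest.approx((0.25 - 0.75) / 0.75)

    def test_bootstrap_deterministic_given_seed(self):
        q = recs("MKEEV", "DDEEG")
        b = recs("MKLV", "DDGG")
        a = composition.enrichment_profile(q, b, n_boot=200, seed=9)
        c = composition.enrichment_profile(q, b, n_boot=200, seed=9)
        assert a.equals(c)


class TestStratify:
    def test_absent_tag_errors(self):
        with pytest.raises(ValueError, match="taxon"):
            composition.stratify(recs("MK", "LV"), "human")

    def test_tag_on_all_is_identity(self):
        rs = recs("MK", "LV", tag="human")
        assert composition.stratify(rs, "human") == rs

    def test_mixed_tags_partition(self):
        rs = recs("MK", tag="human") + recs("LV", "GG", tag="yeast")
        assert len(composition.stratify(rs, "human")) == 1
        assert len(composition.stratify(rs, "yeast")) == 2


def test_drop_exact_duplicates():
    rs = recs("MK", "MK", "LV")
    assert len(composition.drop_exact_duplicates(rs)) == 2
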