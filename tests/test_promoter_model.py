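import math

import numpy as np
import pytest

from tuatlas import promoter_model as pm
from tuatlas import synthetic_data as sd
from tuatlas.core_io import SiteCall


class TestInformationContent:
    def test_identical_hexamers_carry_twelve_bits(self):
        hexes = np.stack([pm.encode("TATAAT")] * 10)
        assert pm.information_content(hexes, correct_small_sample=False) == \
            pytest.approx(12.0)

    def test_equifrequent_positions_carry_zero_bits(self):
        hexes = np.stack([pm.encode(b * 6) for b in "ACGT"])
        assert pm.information_content(hexes, correct_small_sample=False) == \
            pytest.approx(0.0)

    def test_two_distinct_sequences_give_six_bits(self):
        hexes = np.stack([pm.encode("AAAAAA"), pm.encode("CCCCCC")])
        assert pm.information_content(hexes, correct_small_sample=False) == \
            pytest.approx(6.0)

    def test_small_sample_correction_value(self):
        assert pm.small_sample_correction(10) == pytest.approx(
            3.0 / (2.0 * math.log(2.0) * 10.0)
        )


class TestIndividualInformation:
    def test_consensus_of_tight_matrix_nears_twelve_bits(self):
        matrix = pm.InformationMatrix.from_hexamers(
            np.stack([pm.encode("TATAAT")] * 500)
        )
        ri = pm.individual_information(matrix, "TATAAT")
        assert ri == pytest.approx(12.0 - 6 * matrix.e_n, abs=0.05)

    def test_uniform_matrix_scores_near_zero(self):
        matrix = pm.InformationMatrix.from_counts(np.full((4, 6), 25.0), 100)
        assert pm.individual_information(matrix, "ACGTAC") == pytest.approx(
            0.0, abs=6 * matrix.e_n + 1e-9
        )

    def test_agrees_with_direct_formula(self):
        # 8 copies of TATAAT, pseudocount 0.25/base: f = 8.25/9 vs 0.25/9
        matrix = pm.InformationMatrix.from_hexamers(
            np.stack([pm.encode("TATAAT")] * 8)
        )
        e = pm.small_sample_correction(8)
        expected = sum(2.0 + math.log2(8.25 / 9.0) - e for _ in range(6))
        assert pm.individual_information(matrix, "TATAAT") == pytest.approx(
            expected, abs=1e-12
        )
        mismatch = sum(2.0 + math.log2(8.25 / 9.0) - e for _ in range(5)) + (
            2.0 + math.log2(0.25 / 9.0) - e
        )
        assert pm.individual_information(matrix, "AATAAT") == pytest.approx(
            mismatch, abs=1e-12
        )


class TestGapSurprisal:
    def test_single_length_has_zero_penalty(self):
        assert pm.gap_surprisal({17: 100})[17] == 0.0

    def test_half_frequency_costs_one_bit(self):
        gs = pm.gap_surprisal({17: 100, 16: 50})
        assert gs[17] == 0.0 and gs[16] == pytest.approx(1.0)

    def test_quarter_frequency_costs_two_bits(self):
        gs = pm.gap_surprisal({17: 100, 18: 25})
        assert gs[18] == pytest.approx(2.0)

    def test_unobserved_lengths_get_pseudocount(self):
        gs = pm.gap_surprisal({17: 64}, allowed_range=(16, 18))
        assert gs[16] == gs[18] == pytest.approx(math.log2(64 / 0.5))
        assert all(v >= 0 for v in gs.values())


class TestMalign:
    def test_planted_exact_hexamer_recovered(self):
        rng = np.random.default_rng(0)
        windows, offsets_true = [], []
        for _ in range(40):
            w = list(rng.choice(list("ACGT"), size=30))
            o = int(rng.integers(5, 15))
            w[o : o + 6] = "TATAAT"
            windows.append("".join(w))
            offsets_true.append(o)
        offs, matrix = pm.malign(windows, list(range(5, 15)), seed=1)
        assert offs == offsets_true
        assert matrix.r_sequence > 10.0

    def test_forced_offsets_reproduce_count_matrix(self):
        offs, matrix = pm.malign(
            ["AAAAAACG", "CCCCCCGT"], [[1], [1]], seed=0
        )
        assert offs == [1, 1]
        # column frequencies reflect the two forced hexamers (pseudocount
        # 0.25 per base: f(A) = (1 + 0.25) / (2 + 1))
        assert matrix.freq[pm._BASE_INDEX["A"], 0] == pytest.approx(1.25 / 3.0)

    def test_uniform_random_sequences_score_far_below_a_real_motif(self):
        # picking the best of 20 offsets per window inflates apparent
        # information on pure noise (~3.4 bits at n=200); the test pins the
        # property that matters: noise stays far below a planted motif's
        # ~12 bits and the bias shrinks with none of the planted structure
        rs = []
        for seed in range(5):
            windows = [
                "".join(np.random.default_rng(100 * seed + i).choice(
                    list("ACGT"), size=40))
                for i in range(200)
            ]
            _, matrix = pm.malign(windows, list(range(0, 20)), seed=seed)
            rs.append(matrix.r_sequence)
        assert np.mean(rs) < 5.0
        assert max(rs) < 12.0 / 2

    def test_same_seed_same_output(self):
        rng = np.random.default_rng(3)
        windows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(30)]
        a = pm.malign(windows, list(range(0, 10)), seed=42)
        b = pm.malign(windows, list(range(0, 10)), seed=42)
        assert a[0] == b[0]
        assert np.array_equal(a[1].freq, b[1].freq)


class TestMultiscan:
    def _windows(self, n, spacer_probs, seed=0, disc=6):
        return sd.simulate_promoter_set(
            n, spacer_dist=spacer_probs, disc_dist={disc: 1.0}, seed=seed
        )

    @staticmethod
    def _prelim35(windows, o10, assumed_spacer=17):
        # as in the full pipeline: the preliminary -35 profile comes from
        # the positions implied by an assumed spacer
        hexes = [
            pm.encode(w[o - 6 - assumed_spacer : o - assumed_spacer])
            for w, o in zip(windows, o10)
            if o - 6 - assumed_spacer >= 0
        ]
        return pm.InformationMatrix.from_hexamers(np.stack(hexes))

    def test_planted_minus35_found_at_planted_spacer(self):
        windows, truth = self._windows(120, {17: 1.0})
        o10 = [t[1] for t in truth]
        m10 = pm.InformationMatrix.from_hexamers(
            np.stack([pm.encode(w[o : o + 6]) for w, o in zip(windows, o10)])
        )
        model = pm.multiscan(windows, o10, m10, self._prelim35(windows, o10))
        assert model.modal_spacer == 17
        assert set(model.spacer_hist) == {17}
        assert model.minus35.consensus() == "TTGACA"

    def test_spacer_mixture_proportions_recovered(self):
        props = []
        for seed in range(5):
            windows, truth = self._windows(200, {17: 0.8, 15: 0.2}, seed=seed)
            o10 = [t[1] for t in truth]
            m10 = pm.InformationMatrix.from_hexamers(
                np.stack([pm.encode(w[o : o + 6]) for w, o in zip(windows, o10)])
            )
            model = pm.multiscan(windows, o10, m10, self._prelim35(windows, o10))
            props.append(model.spacer_hist.get(17, 0) / sum(model.spacer_hist.values()))
        assert np.mean(props) == pytest.approx(0.8, abs=0.05)

    def test_random_sequence_dropped_as_nonconforming(self):
        windows, truth = self._windows(100, {17: 1.0}, seed=3)
        rng = np.random.default_rng(99)
        junk = "".join(rng.choice(list("ACGT"), size=61))
        windows.append(junk)
        o10 = [t[1] for t in truth] + [48]
        m10 = pm.InformationMatrix.from_hexamers(
            np.stack([pm.encode(w[o : o + 6]) for w, o in zip(windows, o10)])
        )
        prelim = pm.InformationMatrix.from_counts(np.zeros((4, 6)), 2)
        model = pm.multiscan(windows, o10, m10, prelim, drop_nonconforming=True)
        assert model.n_dropped >= 1
        assert f"seq_{len(windows) - 1}" not in {c[0] for c in model.contributing}


class TestWindowExtraction:
    def site(self, pos, strand):
        return SiteCall("chr", pos, strand, "tss_primary", 0.01, 0.01, 1.0)

    def test_plus_strand_window_coordinates(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        genome = {"chr": pm.GenomeSequence("chr", seq)}
        (w,) = pm.extract_promoter_windows([self.site(100, "+")], genome)
        assert w.window == seq[39:100]  # genomic 40..100
        assert len(w.window) == 61

    def test_minus_strand_window_is_reverse_complement(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        genome = {"chr": pm.GenomeSequence("chr", seq)}
        (w,) = pm.extract_promoter_windows([self.site(100, "-")], genome)
        assert w.window == genome["chr"].subseq(100, 160, "-")

    def test_out_of_range_tss_skipped(self):
        genome = {"chr": pm.GenomeSequence("chr", "ACGT" * 50)}
        assert pm.extract_promoter_windows([self.site(30, "+")], genome) == []


class TestFullModel:
    def test_planted_full_consensus_recovered_end_to_end(self):
        windows, truth = sd.simulate_promoter_set(
            300, spacer_dist={17: 0.6, 16: 0.25, 18: 0.15},
            disc_dist={6: 0.6, 7: 0.4}, seed=11,
        )
        model = pm.build_promoter_model(windows, seed=11)
        assert model.minus10.consensus() == "TATAAT"
        assert model.minus35.consensus() == "TTGACA"
        assert model.modal_spacer == 17 and model.modal_discriminator == 6
        # the last -10 position (homologous to the E. coli T at -7) is
        # informative when a full TATAAT is planted
        assert model.minus10.per_position_information[5] > 1.0

    def test_determinism_under_fixed_seed(self):
        windows, _ = sd.simulate_promoter_set(100, seed=2)
        m1 = pm.build_promoter_model(windows, seed=5)
        m2 = pm.build_promoter_model(windows, seed=5)
        assert m1.to_dict() == m2.to_dict()

    def test_too_few_surviving_windows_rejected(self):
        windows, _ = sd.simulate_promoter_set(12, seed=3)
        with pytest.raises(ValueError):
            pm.build_promoter_model(windows[:6], seed=0, min_surviving=10)

    def test_pfm_export_is_logo_ready(self, tmp_path):
        windows, _ = sd.simulate_promoter_set(60, seed=4)
        model = pm.build_promoter_model(windows, seed=4)
        pm.write_pfm(model.minus10, tmp_path / "m10.pfm", "minus10")
        lines = (tmp_path / "m10.pfm").read_text().splitlines()
        assert lines[1].startswith("PO")
        freqs = np.array([[float(x) for x in l.split("\t")[1:]] for l in lines[2:]])
        assert freqs.shape == (4, 6)
        assert np.allclose(freqs.sum(axis=0), 1.0, atol=2e-3)
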