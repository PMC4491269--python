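import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stpscan import PeptideSequence, scan
from stpscan.features import (
    FEATURE_SETS,
    NormalizationParams,
    feature_names,
    featurize,
    fit_normalization,
    interloop_presence,
    least_loop_ratio,
    normalized_proximity,
    proximity_lengths,
    residue_frequencies,
)


class TestProximityLengths:
    def test_toy_motif(self, toy_stp):
        assert proximity_lengths(scan(toy_stp)).as_tuple() == (13, 12, 13)

    def test_invalid_motif_assigned_zero(self):
        m = scan(PeptideSequence("x", "MKVLNNNAA"))
        assert proximity_lengths(m).as_tuple() == (0, 0, 0)

    def test_adjacent_window(self):
        # six consecutive cysteines after a valid anchoring would give
        # P = 2 each; build one that stays valid: loops (3,4,1,2,5)
        s = PeptideSequence("x", "A" + "C" + "AAA" + "C" + "AAAA" + "C" + "A"
                            + "C" + "AA" + "C" + "AAAAA" + "C" + "A")
        m = scan(s)
        assert m.valid
        p = proximity_lengths(m)
        # each P_j spans the two inner loops plus the min loop plus 2 cysteines
        assert p.as_tuple() == (10, 9, 10)


class TestNormalizedProximity:
    def test_peak_at_training_mean(self):
        assert normalized_proximity(13, 13.0) == 10.0

    def test_deviation_of_ten_halves_the_peak(self):
        assert normalized_proximity(23, 13.0) == 5.0
        assert normalized_proximity(3, 13.0) == 5.0

    def test_zero_proximity(self):
        assert normalized_proximity(0, 13.0) == pytest.approx(100 / 23)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 500), st.floats(0, 500))
    def test_bounded_and_peaked(self, P, mean):
        np_val = normalized_proximity(P, mean)
        assert 0 < np_val <= 10
        if P == mean:
            assert np_val == 10
        elif abs(P - mean) > 1e-6:
            assert np_val < 10

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 200), st.floats(0.1, 50), st.floats(0.1, 50))
    def test_strictly_decreasing_in_deviation(self, mean, d1, d2):
        lo, hi = sorted((d1, d2))
        if lo < hi:
            assert normalized_proximity(mean + hi, mean) < normalized_proximity(
                mean + lo, mean
            )


class TestLoopFeatures:
    def test_least_loop_ratio(self, toy_stp):
        assert least_loop_ratio(scan(toy_stp), len(toy_stp)) == pytest.approx(2 / 29)

    def test_ratio_exact_tenth(self):
        s = PeptideSequence("x", "A" * 2 + "CAAAAC" + "AAAA" + "CAAAC"
                            + "AAAA" + "CAAAAAC" + "AA")
        m = scan(s)
        assert m.valid and m.min_loop == 3 and len(s) == 30
        assert least_loop_ratio(m, len(s)) == 0.1

    def test_invalid_motif_ratio_zero(self):
        assert least_loop_ratio(scan(PeptideSequence("x", "AAAA")), 4) == 0.0

    def test_interloop_presence(self, toy_stp):
        assert interloop_presence(scan(toy_stp)) == 1

    def test_interloop_absent_when_last_loop_empty(self):
        # valid motif with dC(4,5) = 0: loops (4,5,1,0,6)
        s = PeptideSequence(
            "x", "A" + "C" + "AAAA" + "C" + "AAAAA" + "C" + "A" + "CC"
            + "AAAAAA" + "C" + "A"
        )
        m = scan(s)
        assert m.valid and m.loops[3] == 0
        assert interloop_presence(m) == 0

    def test_interloop_zero_for_invalid(self):
        assert interloop_presence(scan(PeptideSequence("x", "AAAA"))) == 0


class TestResidueFrequencies:
    @pytest.mark.parametrize(
        "residues, alphabet, expected",
        [
            ("CCSS", "CSHKL", {"C": 0.5, "S": 0.5, "H": 0, "K": 0, "L": 0}),
            ("AAAA", "C", {"C": 0.0}),
            ("GCAAAACAAAAACAACAAACAAAAAACGG", "C", {"C": 6 / 29}),
        ],
    )
    def test_examples(self, residues, alphabet, expected):
        freqs = residue_frequencies(PeptideSequence("x", residues), tuple(alphabet))
        assert freqs == pytest.approx(expected)

    def test_empty_alphabet_rejected(self):
        with pytest.raises(ValueError):
            residue_frequencies(PeptideSequence("x", "AA"), ())


class TestFitNormalization:
    def test_mean_over_two_positives(self, toy_stp):
        # second positive: same loop profile stretched by one in dC(1,2)
        other = PeptideSequence("y", "GC" + "AAAAA" + "AAAAC" + "AAAAA"
                                + "CAAC" + "AAAC" + "AAAAAAC" + "GG")
        m = scan(other)
        assert m.valid
        p1, p2 = proximity_lengths(scan(toy_stp)), proximity_lengths(m)
        params = fit_normalization([toy_stp, other])
        assert params.meanP1 == pytest.approx((p1.P1 + p2.P1) / 2)
        assert params.meanP3 == pytest.approx((p1.P3 + p2.P3) / 2)

    def test_single_positive_mean_is_its_own_p(self, toy_stp):
        assert fit_normalization([toy_stp]).as_tuple() == (13.0, 12.0, 13.0)

    def test_invalid_positives_excluded(self, toy_stp):
        params_with_junk = fit_normalization([toy_stp, PeptideSequence("z", "AAAA")])
        assert params_with_junk == fit_normalization([toy_stp])

    def test_error_when_no_valid_motif(self):
        with pytest.raises(ValueError):
            fit_normalization([PeptideSequence("z", "AAAA")])


class TestFeaturize:
    params = NormalizationParams(13.0, 12.0, 13.0)

    def test_toy_vector_set_6(self, toy_stp):
        vec = featurize(toy_stp, 6, self.params)
        names = feature_names(6)
        expected = {
            "NP1": 10.0, "NP2": 10.0, "NP3": 10.0,
            "least_loop_ratio": 2 / 29, "interloop_flag": 1.0,
            "freq_C": 6 / 29, "freq_S": 0.0, "freq_H": 0.0,
            "freq_K": 0.0, "freq_L": 0.0,
        }
        assert dict(zip(names, vec)) == pytest.approx(expected)

    def test_no_cysteine_sequence(self):
        vec = featurize(PeptideSequence("x", "SSHHKKLLAA"), 6, self.params)
        by_name = dict(zip(feature_names(6), vec))
        assert by_name["NP1"] == pytest.approx(100 / 23)
        assert by_name["NP2"] == pytest.approx(100 / 22)
        assert by_name["least_loop_ratio"] == 0.0
        assert by_name["interloop_flag"] == 0.0
        assert by_name["freq_S"] == pytest.approx(0.2)

    def test_deterministic(self, toy_stp):
        v1 = featurize(toy_stp, 6, self.params)
        v2 = featurize(toy_stp, 6, self.params)
        assert np.array_equal(v1, v2)

    def test_unknown_feature_set(self, toy_stp):
        with pytest.raises(ValueError, match="unknown feature set"):
            featurize(toy_stp, 7, self.params)

    @pytest.mark.parametrize("fsid", sorted(FEATURE_SETS))
    def test_layout_matches_declaration(self, toy_stp, fsid):
        assert featurize(toy_stp, fsid, self.params).shape == (
            len(feature_names(fsid)),
        )
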