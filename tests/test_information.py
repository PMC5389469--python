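"""The information-theory core: e(n), matrices, Ri scoring, distances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ipwmkit as k
from ipwmkit.information import position_entropies
from tests.conftest import random_alignment


class TestSmallSampleCorrection:
    def test_single_draw_has_full_correction(self):
        assert k.small_sample_correction(1) == pytest.approx(2.0)

    def test_two_draws_matches_enumeration(self):
        # oracle: enumerate all 16 ordered pairs of 4 letters and average
        # the plug-in entropy of each pair
        expected = 2.0 - np.mean(
            [
                0.0 if a == b else 1.0
                for a, b in itertools.product(range(4), repeat=2)
            ]
        )
        assert k.small_sample_correction(2) == pytest.approx(expected)
        assert expected == pytest.approx(1.25)

    def test_matches_multinomial_enumeration_small_n(self):
        # independent oracle: full multinomial enumeration over compositions
        from math import comb, factorial

        for n in (3, 5, 8):
            total = 0.0
            for c in itertools.product(range(n + 1), repeat=3):
                if sum(c) > n:
                    continue
                counts = (*c, n - sum(c))
                coef = factorial(n) / np.prod([factorial(x) for x in counts])
                p = coef * 0.25**n
                f = np.array(counts) / n
                h = -np.sum([x * np.log2(x) for x in f if x > 0])
                total += p * h
            assert k.small_sample_correction(n) == pytest.approx(2 - total, abs=1e-12)

    def test_monotone_and_vanishing(self):
        vals = [k.small_sample_correction(n) for n in (1, 2, 5, 20, 100, 1000)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert k.small_sample_correction(10**6) < 1e-5

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            k.small_sample_correction(0)


class TestFrequencyMatrix:
    def test_four_distinct_bases_give_uniform_column(self):
        sites = k.AlignedSites(
            ["A", "C", "G", "T"], k.contiguous(1), [0] * 4, ["+"] * 4
        )
        fm = k.build_frequency_matrix(sites)
        assert np.allclose(fm.freqs[:, 0], 0.25)

    def test_single_site_gives_unit_vectors(self):
        sites = k.AlignedSites(["ACG"], k.contiguous(3), [0], ["+"])
        fm = k.build_frequency_matrix(sites)
        assert np.allclose(fm.freqs.sum(axis=0), 1.0)
        assert fm.freqs[0, 0] == 1.0 and fm.freqs[1, 1] == 1.0 and fm.freqs[2, 2] == 1.0

    def test_reverse_strand_site_enters_as_revcomp(self):
        # "GT" on the minus strand reads "AC": both sites agree
        sites = k.AlignedSites(["AC", "GT"], k.contiguous(2), [0, 0], ["+", "-"])
        fm = k.build_frequency_matrix(sites)
        assert fm.freqs[0, 0] == 1.0  # f(A, 0) = 1
        assert fm.freqs[1, 1] == 1.0

    def test_zero_sites_error(self):
        sites = k.AlignedSites(
            ["ACGT"], k.contiguous(2), [0], ["+"], included=[False]
        )
        with pytest.raises(ValueError):
            k.build_frequency_matrix(sites)


class TestBuildIpwm:
    def test_conserved_position_near_two_bits(self):
        f = np.zeros((4, 1))
        f[0, 0] = 1.0
        m = k.build_ipwm(k.FrequencyMatrix(f, n=100_000))
        assert m.weights[0, 0] == pytest.approx(2.0, abs=1e-3)
        assert m.rsequence == pytest.approx(2.0, abs=1e-3)

    def test_uniform_column_near_zero(self):
        m = k.build_ipwm(k.FrequencyMatrix(np.full((4, 1), 0.25), n=100_000))
        assert np.allclose(m.weights, 0.0, atol=1e-3)

    def test_counts_2110_matches_hand_formula(self):
        # direct evaluation of w = 2 + log2((c + 0.25)/(n + 1)) - e(n), n=4
        counts = np.array([2.0, 1.0, 1.0, 0.0])
        m = k.build_ipwm(k.FrequencyMatrix((counts / 4)[:, None], n=4))
        e4 = k.small_sample_correction(4)
        expected = 2 + np.log2((counts + 0.25) / 5.0) - e4
        assert np.allclose(m.weights[:, 0], expected)
        # entropies from raw frequencies, not pseudocounted ones
        assert m.entropies[0] == pytest.approx(1.5)


class TestScoring:
    def test_identical_training_sites_score_rsequence(self):
        sites = k.AlignedSites(["ACGTAC"] * 10, k.contiguous(6), [0] * 10, ["+"] * 10)
        m = k.build_ipwm(k.build_frequency_matrix(sites))
        assert k.score_site(m, "ACGTAC", 0) == pytest.approx(m.rsequence)

    @pytest.mark.parametrize("pattern", [k.contiguous(8), k.bipartite(4, 1, 3, 4)])
    def test_mean_training_ri_equals_rsequence(self, rng, pattern):
        """Definitional identity: Rsequence is the mean Ri of training sites."""
        for seed in range(5):
            al = random_alignment(np.random.default_rng(seed), pattern=pattern)
            model = k.ipwm_from_sites(al)
            ris = []
            for i in range(len(al)):
                if pattern.kind == "contiguous":
                    ris.append(
                        k.score_site(model, al.sequences[i], int(al.offsets[i]),
                                     al.strands[i])
                    )
                else:
                    ris.append(
                        k.score_bipartite(model, al.sequences[i], int(al.offsets[i]),
                                          int(al.gaps[i]), al.strands[i])
                    )
            assert np.mean(ris) == pytest.approx(model.rsequence, abs=1e-9)

    def test_reverse_complement_consistency(self, rng):
        al = random_alignment(rng, n_seqs=20)
        m = k.ipwm_from_sites(al)
        seq = "".join(rng.choice(list("ACGT"), size=30))
        from ipwmkit.seq import revcomp

        for off in range(0, 10):
            plus = k.score_site(m, seq, off, "-")
            mirrored = k.score_site(m, revcomp(seq), len(seq) - off - m.length, "+")
            assert plus == pytest.approx(mirrored, abs=1e-12)

    def test_n_in_window_raises(self):
        sites = k.AlignedSites(["ACGT"] * 4, k.contiguous(4), [0] * 4, ["+"] * 4)
        m = k.build_ipwm(k.build_frequency_matrix(sites))
        with pytest.raises(ValueError):
            k.score_site(m, "ACNT", 0)

    def test_affinity_fold_of_printed_ri_pair(self):
        assert k.affinity_fold(9.02, 6.89) == pytest.approx(2**2.13)
        assert k.affinity_fold(9.02, 6.89) == pytest.approx(4.38, abs=0.01)


class TestBipartiteScoring:
    def _palindromic_model(self):
        sites, gaps = [], []
        for gap, count in [(1, 2), (2, 6), (3, 2)]:
            for _ in range(count):
                sites.append("AGGTCA" + "T" * gap + "TGACCT")
                gaps.append(gap)
        pat = k.bipartite(6, 1, 3, 6)
        al = k.AlignedSites(
            sites, pat, offsets=[0] * len(sites), strands=["+"] * len(sites),
            gaps=gaps,
        )
        return k.ipwm_from_sites(al)

    def test_consensus_scores_sum_of_half_rsequences(self):
        bm = self._palindromic_model()
        ri = k.score_bipartite(bm, "AGGTCA" + "TT" + "TGACCT", 0, 2)
        assert ri == pytest.approx(bm.left.rsequence + bm.right.rsequence)

    def test_uniform_gap_histogram_contributes_zero(self):
        bm = self._palindromic_model()
        bm.gap_hist = np.array([5.0, 5.0, 5.0])
        for gap in (1, 2, 3):
            assert bm.gap_information(gap) == pytest.approx(0.0)

    def test_gap_outside_range_errors(self):
        bm = self._palindromic_model()
        with pytest.raises(ValueError):
            k.score_bipartite(bm, "AGGTCA" + "TTTTT" + "TGACCT", 0, 5)

    def test_dominant_gap_ties_break_small(self):
        bm = self._palindromic_model()
        bm.gap_hist = np.array([4.0, 4.0, 2.0])
        assert bm.dominant_gap == 1


class TestEuclideanDistance:
    def _model_from(self, weights):
        w = np.asarray(weights, dtype=float)
        return k.InformationWeightMatrix(
            weights=w, freqs=np.full_like(w, 0.25), n=10, e_n=0.0,
            rsequence=0.0, entropies=position_entropies(np.full_like(w, 0.25)),
        )

    def test_self_distance_zero(self, rng):
        m = self._model_from(rng.normal(size=(4, 6)))
        assert k.euclidean_distance(m, m) == 0.0

    def test_palindromic_matrix_revcomp_distance_zero(self):
        w = np.zeros((4, 2))
        w[0, 0] = 1.5  # A at position 0
        w[3, 1] = 1.5  # T at position 1: perfect palindrome
        m = self._model_from(w)
        assert k.euclidean_distance(m, m.reverse_complement()) == 0.0

    def test_single_bit_difference_two_positions(self):
        # one weight differs by 1 bit in a 2-position matrix: d = 1/2 bit/nt.
        # weights chosen so the reverse-complement branch is farther.
        w1 = np.zeros((4, 2))
        w1[0, 0] = 3.0
        w1[1, 1] = -2.0
        w2 = w1.copy()
        w2[0, 0] = 4.0
        assert k.euclidean_distance(
            self._model_from(w1), self._model_from(w2)
        ) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 6))
    def test_metric_properties(self, seed, L):
        r = np.random.default_rng(seed)
        a, b, c = (self._model_from(r.normal(size=(4, L))) for _ in range(3))
        dab = k.euclidean_distance(a, b)
        assert dab == pytest.approx(k.euclidean_distance(b, a))
        assert dab <= k.euclidean_distance(a, c) + k.euclidean_distance(c, b) + 1e-12

    def test_unequal_lengths_best_overlap(self, rng):
        w = rng.normal(size=(4, 8))
        long = self._model_from(w)
        short = self._model_from(w[:, 2:6])  # exact sub-block: distance 0
        assert k.euclidean_distance(long, short) == pytest.approx(0.0, abs=1e-12)


class TestDeltaRi:
    def _model(self):
        w = np.zeros((4, 1))
        w[0, 0] = 2.0
        w[1, 0] = -3.0
        return k.InformationWeightMatrix(
            weights=w, freqs=np.full((4, 1), 0.25), n=5, e_n=0.0,
            rsequence=0.0, entropies=np.array([2.0]),
        )

    def test_same_base_zero(self):
        m = self._model()
        assert k.delta_ri(m, "A", 0, "A", "A").delta == 0.0

    def test_outside_window_flagged(self):
        m = self._model()
        res = k.delta_ri(m, "A", 5, "A", "C")
        assert res.delta == 0.0 and res.outside

    def test_a_to_c_from_known_weights(self):
        m = self._model()
        assert k.delta_ri(m, "A", 0, "A", "C").delta == pytest.approx(-5.0)

    def test_reference_mismatch_errors(self):
        m = self._model()
        with pytest.raises(ValueError):
            k.delta_ri(m, "A", 0, "G", "C")
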